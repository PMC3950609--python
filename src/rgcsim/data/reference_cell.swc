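# SWC written by rgcsim (synthetic coordinates)
1 1 0 0 0 8.15 -1
2 3 -37.838151 34.6628459 29.413097 0.75 1
3 3 -32.2622232 -28.8719761 17.6241405 0.525 2
4 3 -7.48652341 3.44353692 -25.0229277 0.3675 3
5 3 -59.2648352 -33.648358 -10.6145045 0.3675 3
6 3 16.9392706 -0.182065936 18.3059677 0.525 2
7 3 3.44056412 50.0324493 48.9522376 0.3675 6
8 3 3.50786053 -26.0434287 57.1457254 0.3675 6
9 3 50.853654 18.5716729 30.1612879 0.75 1
10 3 -2.97746452 40.7923761 18.5929661 0.525 9
11 3 14.0061615 4.49935373 -24.0694984 0.3675 10
12 3 8.66337235 77.9051984 -20.7740635 0.3675 10
13 3 -1.76163597 -11.9199631 20.5908422 0.525 9
14 3 36.8018176 -20.3980302 44.5066014 0.3675 13
15 3 -20.0846932 14.1427003 63.0029128 0.3675 13
16 3 -5.56235521 -42.9243112 23.4230109 0.75 1
17 3 40.9497153 -3.72388896 10.4973771 0.525 16
18 3 3.32559722 -2.16801356 -30.2416139 0.3675 17
19 3 66.8308037 -29.4790287 -25.8084845 0.3675 17
20 3 -7.64804797 2.18071778 16.9341037 0.525 16
21 3 -35.8900145 -31.6625969 44.3576869 0.3675 20
22 3 25.1893031 6.59893691 60.9561998 0.3675 20
23 3 -37.5646094 26.1364768 24.0401055 0.75 1
24 3 -22.4669613 -40.9740826 8.46638912 0.525 23
25 3 -0.0191942495 -1.79973601 -41.1449758 0.3675 24
26 3 -37.7803348 -45.8594664 -7.22937562 0.3675 24
27 3 -8.45924981 12.6890624 19.8696093 0.525 23
28 3 -25.6716362 53.8171797 48.3461099 0.3675 27
29 3 -18.6399892 -15.6159866 59.7262605 0.3675 27
30 2 -30 0 0 0.5 1
31 2 -40 0 0 0.5 30
32 2 -70 0 0 0.2 31
33 2 -130 0 0 0.2 32
34 2 -5470 0 0 0.5 33
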