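# synthetic closed-curve coordinates for knot 10_124
# generated by helknot's parametric/braid/pretzel builders and
# verified against the Alexander invariant table; columns: x y z (sigma)
9.126549 0.000000 0.000000
9.040424 0.976782 0.196162
8.861588 1.940891 0.392404
8.590691 2.883542 0.587403
8.173266 3.771608 0.780004
7.657477 4.606780 0.970922
7.060622 5.386689 1.159349
6.361784 6.077856 1.343508
5.572348 6.664799 1.523195
4.724479 7.165070 1.698830
3.825813 7.569277 1.869173
2.870549 7.816896 2.030898
1.891345 7.947675 2.186002
0.902358 7.960310 2.333464
-0.081706 7.848705 2.471892
-1.037419 7.582742 2.597892
-1.945179 7.178858 2.711251
-2.790109 6.653459 2.811496
-3.551835 6.011173 2.896594
-4.209212 5.260658 2.964287
-4.741285 4.415307 3.012048
-5.128461 3.493639 3.037007
-5.353899 2.519383 3.035912
-5.405087 1.521168 3.005122
-5.275501 0.531698 2.940652
-4.966175 -0.413735 2.838308
-4.486893 -1.279438 2.693929
-3.849692 -2.025589 2.500966
-3.074088 -2.604706 2.249844
-2.216056 -3.018417 1.945501
-1.309060 -3.218857 1.575122
-0.403976 -3.238675 1.150350
0.463164 -3.082700 0.677338
1.265893 -2.766384 0.171798
1.995220 -2.313814 -0.341293
2.637552 -1.730348 -0.838260
3.172215 -1.021946 -1.299023
3.552699 -0.190487 -1.703878
3.765316 0.722302 -2.052604
3.775737 1.680290 -2.339223
3.596306 2.636089 -2.572147
3.200450 3.537644 -2.746779
2.636844 4.353392 -2.876792
1.927081 5.052151 -2.966081
1.098977 5.610231 -3.018904
0.183345 6.011727 -3.039402
-0.788204 6.248430 -3.031458
-1.785166 6.319046 -2.998585
-2.779518 6.228089 -2.943906
-3.746627 5.984649 -2.870168
-4.665735 5.601144 -2.779803
-5.520103 5.092157 -2.674990
-6.296752 4.473237 -2.557704
-6.963202 3.739227 -2.427044
-7.517367 2.918948 -2.285465
-7.965463 2.037663 -2.135312
-8.306048 1.110706 -1.977979
-8.513463 0.146437 -1.813163
-8.576149 -0.836622 -1.640928
-8.531685 -1.819806 -1.463805
-8.384503 -2.792262 -1.283068
-8.080463 -3.726607 -1.097164
-7.673409 -4.620160 -0.907769
-7.180123 -5.468696 -0.716313
-6.573856 -6.240052 -0.522793
-5.870626 -6.923591 -0.327236
-5.105227 -7.536458 -0.130872
-4.270792 -8.051420 0.065422
-3.369138 -8.436741 0.261758
-2.434711 -8.734132 0.457731
-1.473554 -8.930137 0.652046
-0.492755 -8.965151 0.843898
0.487053 -8.903594 1.034126
1.456233 -8.743588 1.221445
2.387787 -8.428968 1.403714
3.276803 -8.007310 1.582194
4.116123 -7.492272 1.756200
4.884529 -6.874692 1.923969
5.545500 -6.141411 2.083394
6.117253 -5.335322 2.236103
6.587383 -4.464652 2.380706
6.943293 -3.539949 2.515815
7.134900 -2.565982 2.636950
7.194317 -1.573740 2.746155
7.114811 -0.581485 2.841597
6.891046 0.389905 2.921166
6.521235 1.316984 2.982523
6.008106 2.174338 3.023033
5.359784 2.935522 3.039702
4.590491 3.574331 3.029148
3.720950 4.066441 2.987605
2.778315 4.391359 2.910999
1.795429 4.534561 2.795117
0.809216 4.489554 2.635875
-0.135012 4.238161 2.423190
-0.993683 3.801765 2.154409
-1.732270 3.211816 1.828143
-2.310064 2.493898 1.439880
-2.717879 1.695859 0.996236
-2.959940 0.856026 0.510349
-3.042183 0.000000 0.000000
-2.959940 -0.856026 -0.510349
-2.717879 -1.695859 -0.996236
-2.310064 -2.493898 -1.439880
-1.732270 -3.211816 -1.828143
-0.993683 -3.801765 -2.154409
-0.135012 -4.238161 -2.423190
0.809216 -4.489554 -2.635875
1.795429 -4.534561 -2.795117
2.778315 -4.391359 -2.910999
3.720950 -4.066441 -2.987605
4.590491 -3.574331 -3.029148
5.359784 -2.935522 -3.039702
6.008106 -2.174338 -3.023033
6.521235 -1.316984 -2.982523
6.891046 -0.389905 -2.921166
7.114811 0.581485 -2.841597
7.194317 1.573740 -2.746155
7.134900 2.565982 -2.636950
6.943293 3.539949 -2.515815
6.587383 4.464652 -2.380706
6.117253 5.335322 -2.236103
5.545500 6.141411 -2.083394
4.884529 6.874692 -1.923969
4.116123 7.492272 -1.756200
3.276803 8.007310 -1.582194
2.387787 8.428968 -1.403714
1.456233 8.743588 -1.221445
0.487053 8.903594 -1.034126
-0.492755 8.965151 -0.843898
-1.473554 8.930137 -0.652046
-2.434711 8.734132 -0.457731
-3.369138 8.436741 -0.261758
-4.270792 8.051420 -0.065422
-5.105227 7.536458 0.130872
-5.870626 6.923591 0.327236
-6.573856 6.240052 0.522793
-7.180123 5.468696 0.716313
-7.673409 4.620160 0.907769
-8.080463 3.726607 1.097164
-8.384503 2.792262 1.283068
-8.531685 1.819806 1.463805
-8.576149 0.836622 1.640928
-8.513463 -0.146437 1.813163
-8.306048 -1.110706 1.977979
-7.965463 -2.037663 2.135312
-7.517367 -2.918948 2.285465
-6.963202 -3.739227 2.427044
-6.296752 -4.473237 2.557704
-5.520103 -5.092157 2.674990
-4.665735 -5.601144 2.779803
-3.746627 -5.984649 2.870168
-2.779518 -6.228089 2.943906
-1.785166 -6.319046 2.998585
-0.788204 -6.248430 3.031458
0.183345 -6.011727 3.039402
1.098977 -5.610231 3.018904
1.927081 -5.052151 2.966081
2.636844 -4.353392 2.876792
3.200450 -3.537644 2.746779
3.596306 -2.636089 2.572147
3.775737 -1.680290 2.339223
3.765316 -0.722302 2.052604
3.552699 0.190487 1.703878
3.172215 1.021946 1.299023
2.637552 1.730348 0.838260
1.995220 2.313814 0.341293
1.265893 2.766384 -0.171798
0.463164 3.082700 -0.677338
-0.403976 3.238675 -1.150350
-1.309060 3.218857 -1.575122
-2.216056 3.018417 -1.945501
-3.074088 2.604706 -2.249844
-3.849692 2.025589 -2.500966
-4.486893 1.279438 -2.693929
-4.966175 0.413735 -2.838308
-5.275501 -0.531698 -2.940652
-5.405087 -1.521168 -3.005122
-5.353899 -2.519383 -3.035912
-5.128461 -3.493639 -3.037007
-4.741285 -4.415307 -3.012048
-4.209212 -5.260658 -2.964287
-3.551835 -6.011173 -2.896594
-2.790109 -6.653459 -2.811496
-1.945179 -7.178858 -2.711251
-1.037419 -7.582742 -2.597892
-0.081706 -7.848705 -2.471892
0.902358 -7.960310 -2.333464
1.891345 -7.947675 -2.186002
2.870549 -7.816896 -2.030898
3.825813 -7.569277 -1.869173
4.724479 -7.165070 -1.698830
5.572348 -6.664799 -1.523195
6.361784 -6.077856 -1.343508
7.060622 -5.386689 -1.159349
7.657477 -4.606780 -0.970922
8.173266 -3.771608 -0.780004
8.590691 -2.883542 -0.587403
8.861588 -1.940891 -0.392404
9.040424 -0.976782 -0.196162
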