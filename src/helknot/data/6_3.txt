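# synthetic closed-curve coordinates for knot 6_3
# generated by helknot's parametric/braid/pretzel builders and
# verified against the Alexander invariant table; columns: x y z (sigma)
1.954558 0.000000 0.000000
2.348617 0.472870 -0.788117
2.742675 0.945741 -1.576235
3.187106 0.834386 -2.465097
3.579644 0.384022 -3.267030
3.734111 -0.123420 -4.114766
3.398790 -0.608105 -4.922624
3.000481 -1.050470 -5.726167
2.576547 -0.732685 -6.574252
2.186578 -0.277788 -7.374883
1.988506 -0.040720 -8.325979
1.957033 -0.002969 -9.324778
1.954662 -0.000125 -10.324780
1.959658 0.006114 -11.324757
2.234325 0.335720 -12.228037
2.611809 0.786533 -13.036917
3.055778 0.864409 -13.929570
3.473531 0.507959 -14.765288
3.870164 0.045983 -15.558558
4.264359 -0.426315 -16.346950
4.661920 -0.884293 -17.142073
5.108026 -0.814148 -18.034283
5.501121 -0.404705 -18.857593
5.610028 0.101058 -19.713368
5.346797 0.590726 -20.544594
4.940113 0.934781 -21.390908
4.507148 0.692516 -22.259132
4.127496 0.261175 -23.077558
3.949928 0.047974 -24.038295
3.912658 -0.080181 -25.029355
3.909129 -1.017698 -25.377033
3.909116 -2.017220 -25.408018
3.909116 -3.017228 -25.409195
3.909116 -4.017223 -25.403888
3.909116 -5.010746 -25.290770
3.909116 -5.580197 -24.468797
3.909116 -5.664066 -23.472313
3.909116 -5.668188 -22.472312
3.909116 -5.668218 -21.472303
3.909116 -5.668218 -20.472294
3.909116 -5.668218 -19.472286
3.909116 -5.668218 -18.472277
3.909116 -5.668218 -17.472268
3.909116 -5.668218 -16.472259
3.909116 -5.668218 -15.472250
3.909116 -5.668218 -14.472241
3.909116 -5.668218 -13.472232
3.909116 -5.668218 -12.472223
3.909116 -5.668218 -11.472214
3.909116 -5.668218 -10.472206
3.909116 -5.668218 -9.472197
3.909116 -5.668218 -8.472188
3.909116 -5.668218 -7.472179
3.909116 -5.668218 -6.472170
3.909116 -5.668218 -5.472161
3.909116 -5.668218 -4.472152
3.909116 -5.668218 -3.472143
3.909116 -5.668218 -2.472135
3.909116 -5.668218 -1.472126
3.909116 -5.668218 -0.472117
3.909116 -5.668218 0.527892
3.909116 -5.304500 1.459380
3.909116 -4.403503 1.892995
3.909116 -3.405256 1.952139
3.909116 -2.405248 1.953542
3.909115 -1.405638 1.925299
3.906849 -0.453013 1.621160
3.848144 -0.120822 0.679820
3.658217 -0.299693 -0.285554
3.318688 -0.655775 -1.156152
2.891900 -0.859180 -2.037318
2.491338 -0.572990 -2.907750
2.269615 -0.092310 -3.756147
2.388132 0.399109 -4.618969
2.748520 0.745256 -5.485160
3.190994 0.731338 -6.381823
3.605277 0.355050 -7.210553
4.001650 -0.108047 -8.003299
4.404423 -0.542612 -8.808866
4.837191 -0.789233 -9.675975
5.267634 -0.635280 -10.565373
5.613786 -0.294509 -11.439482
5.812738 -0.061008 -12.391274
5.858806 -0.003065 -13.388539
5.843800 0.023674 -14.388078
5.742468 0.144597 -15.375563
5.482648 0.438312 -16.295478
5.097234 0.755882 -17.161863
4.656216 0.767717 -18.059289
4.301694 0.375254 -18.907990
4.203238 -0.129056 -19.765889
4.467525 -0.582243 -20.617230
4.885783 -0.802627 -21.498423
5.315424 -0.609971 -22.380632
5.657966 -0.247893 -23.247568
5.839925 -0.090991 -24.218279
5.863662 -0.541160 -25.110883
5.863674 -1.495630 -25.409148
5.863674 -2.495634 -25.409252
5.863674 -3.495643 -25.409212
5.863674 -4.495651 -25.407534
5.863674 -5.495137 -25.375215
5.863674 -6.450793 -25.080726
5.863674 -6.976740 -24.230254
5.863674 -7.036397 -23.232045
5.863674 -7.036408 -22.232037
5.863674 -7.036408 -21.232028
5.863674 -7.036408 -20.232019
5.863674 -7.036408 -19.232010
5.863674 -7.036408 -18.232001
5.863674 -7.036408 -17.231992
5.863674 -7.036408 -16.231983
5.863674 -7.036408 -15.231974
5.863674 -7.036408 -14.231966
5.863674 -7.036408 -13.231957
5.863674 -7.036408 -12.231948
5.863674 -7.036408 -11.231939
5.863674 -7.036408 -10.231930
5.863674 -7.036408 -9.231921
5.863674 -7.036408 -8.231912
5.863674 -7.036408 -7.231903
5.863674 -7.036408 -6.231895
5.863674 -7.036408 -5.231886
5.863674 -7.036408 -4.231877
5.863674 -7.036408 -3.231868
5.863674 -7.036408 -2.231859
5.863674 -7.036328 -1.231850
5.863674 -7.033110 -0.231846
5.863674 -6.976555 0.766561
5.863674 -6.528348 1.660411
5.863674 -5.566207 1.932029
5.863674 -4.566459 1.954510
5.863674 -3.566450 1.954552
5.863674 -2.566442 1.954094
5.863674 -1.566537 1.939672
5.863674 -0.586594 1.740376
5.863674 -0.020752 0.915967
5.863674 -0.000012 -0.083826
5.863674 0.000000 -1.083835
5.863674 0.000000 -2.083844
5.863674 0.000000 -3.083853
5.863670 0.000005 -4.083861
5.863485 0.000226 -5.083870
5.859663 0.004811 -6.083861
5.822993 0.048638 -7.082236
5.656024 0.244550 -8.048543
5.311706 0.608808 -8.913855
4.880337 0.843807 -9.784895
4.442723 0.637821 -10.660133
4.048152 0.167101 -11.449274
3.652896 -0.300744 -12.239787
3.245632 -0.713690 -13.054422
2.803373 -0.839762 -13.942404
2.395334 -0.526232 -14.799834
2.084441 -0.155853 -15.675152
1.955663 -0.001326 -16.654714
1.954561 -0.000004 -17.654718
1.954558 -0.000000 -18.654727
1.954558 -0.000000 -19.654736
1.954558 0.000000 -20.654745
1.954558 -0.000000 -21.654754
1.954558 -0.000010 -22.654762
1.954558 -0.001626 -23.654770
1.954558 -0.063877 -24.652839
1.954558 -0.732528 -25.396312
1.954558 -1.732435 -25.408285
1.954558 -2.732296 -25.391111
1.954558 -3.710889 -25.185678
1.954558 -4.266654 -24.354448
1.954558 -4.300027 -23.354997
1.954558 -4.300027 -22.354988
1.954558 -4.300027 -21.354979
1.954558 -4.300027 -20.354970
1.954558 -4.300027 -19.354961
1.954558 -4.300027 -18.354952
1.954558 -4.300027 -17.354944
1.954558 -4.300027 -16.354935
1.954558 -4.300027 -15.354926
1.954558 -4.300027 -14.354917
1.954558 -4.300027 -13.354908
1.954558 -4.300027 -12.354899
1.954558 -4.300027 -11.354890
1.954558 -4.300027 -10.354881
1.954558 -4.300027 -9.354873
1.954558 -4.300027 -8.354864
1.954558 -4.300027 -7.354855
1.954558 -4.300027 -6.354846
1.954558 -4.300027 -5.354837
1.954558 -4.300027 -4.354828
1.954558 -4.300027 -3.354819
1.954558 -4.300027 -2.354810
1.954558 -4.300027 -1.354801
1.954558 -4.300027 -0.354793
1.954558 -4.299979 0.645216
1.954558 -4.282986 1.645059
1.954558 -3.330490 1.949638
1.954558 -2.330493 1.954458
1.954558 -1.330484 1.954541
1.954558 -0.330572 1.943797
1.954558 0.000000 1.000009
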