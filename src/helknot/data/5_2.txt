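# synthetic closed-curve coordinates for knot 5_2
# generated by helknot's parametric/braid/pretzel builders and
# verified against the Alexander invariant table; columns: x y z (sigma)
1.942653 0.000000 0.000000
2.336745 0.472911 -0.788185
2.730837 0.945821 -1.576369
3.174911 0.827199 -2.464516
3.566109 0.371865 -3.264377
3.714972 -0.136438 -4.112683
3.367594 -0.618895 -4.916797
2.967557 -1.059195 -5.720719
2.547467 -0.716890 -6.560983
2.167090 -0.247368 -7.357877
2.213326 0.266394 -8.214593
2.570922 0.733882 -9.023102
3.006192 0.948180 -9.897596
3.417749 0.557320 -10.720802
3.827852 0.158244 -11.541010
4.254151 0.459933 -12.393607
4.662960 0.865582 -13.211226
5.109040 0.801796 -14.103920
5.501275 0.389414 -14.926204
5.784702 0.051849 -15.823913
5.825856 0.002523 -16.821849
5.827677 -0.000208 -17.821936
5.800099 -0.033429 -18.821096
5.600939 -0.272362 -19.771527
5.236315 -0.692238 -20.602684
4.807625 -0.955666 -21.466957
4.390989 -0.598373 -22.302569
4.036116 -0.180726 -23.139118
3.905797 -0.027644 -24.118683
3.886385 -0.206401 -25.102382
3.885314 -1.194475 -25.249852
3.885306 -2.194557 -25.254414
3.885306 -3.194651 -25.254483
3.885306 -4.194744 -25.253286
3.885306 -5.185706 -25.118486
3.885306 -5.609240 -24.212877
3.885306 -5.633280 -23.213103
3.885306 -5.633690 -22.213009
3.885306 -5.633693 -21.212915
3.885306 -5.633693 -20.212821
3.885306 -5.633693 -19.212727
3.885306 -5.633693 -18.212633
3.885306 -5.633693 -17.212539
3.885306 -5.633693 -16.212445
3.885306 -5.633693 -15.212351
3.885306 -5.633693 -14.212257
3.885306 -5.633693 -13.212163
3.885306 -5.633693 -12.212069
3.885306 -5.633693 -11.211975
3.885306 -5.633693 -10.211881
3.885306 -5.633693 -9.211787
3.885306 -5.633693 -8.211693
3.885306 -5.633693 -7.211599
3.885306 -5.633693 -6.211505
3.885306 -5.633693 -5.211411
3.885306 -5.633693 -4.211317
3.885306 -5.633693 -3.211223
3.885306 -5.633693 -2.211128
3.885306 -5.633693 -1.211034
3.885306 -5.633693 -0.210940
3.885306 -5.630065 0.789147
3.885306 -5.129101 1.654086
3.885306 -4.164957 1.916162
3.885306 -3.165238 1.941526
3.885306 -2.165144 1.942123
3.885288 -1.165580 1.909601
3.883038 -0.256303 1.493616
3.819949 -0.096569 0.509375
3.604492 -0.335630 -0.437416
3.239875 -0.729025 -1.281463
2.803655 -0.897249 -2.165504
2.412824 -0.519347 -3.004753
2.206366 -0.022972 -3.848037
2.386721 0.468505 -4.700081
2.778311 0.812799 -5.553456
3.220659 0.740760 -6.447443
3.575328 0.297870 -7.270961
3.637377 -0.212220 -8.128931
3.289806 -0.658214 -8.953830
2.854866 -0.854074 -9.832787
2.435056 -0.579157 -10.697866
2.103012 -0.192221 -11.558207
1.949575 -0.008305 -12.529186
1.943722 -0.001283 -13.529238
1.959719 -0.020465 -14.529019
2.078475 -0.162272 -15.511854
2.382230 -0.512154 -16.398140
2.793048 -0.858700 -17.241507
3.238076 -0.763946 -18.132066
3.634505 -0.300908 -18.924927
4.028901 0.170734 -19.713719
4.428546 0.619724 -20.513017
4.861543 0.868608 -21.379436
5.292243 0.633787 -22.250949
5.649914 0.212147 -23.084292
5.821987 -0.022104 -24.041215
5.827959 -0.330479 -24.991302
5.827959 -1.295223 -25.254487
5.827959 -2.295317 -25.254487
5.827959 -3.295411 -25.254478
5.827959 -4.295505 -25.254081
5.827959 -5.295527 -25.243873
5.827959 -6.283769 -25.096272
5.827959 -6.931599 -24.335775
5.827959 -6.993550 -23.337611
5.827959 -6.993550 -22.337517
5.827959 -6.993550 -21.337423
5.827959 -6.993550 -20.337329
5.827959 -6.993550 -19.337235
5.827959 -6.993550 -18.337141
5.827959 -6.993550 -17.337047
5.827959 -6.993550 -16.336953
5.827959 -6.993550 -15.336859
5.827959 -6.993550 -14.336765
5.827959 -6.993550 -13.336671
5.827959 -6.993550 -12.336577
5.827959 -6.993550 -11.336483
5.827959 -6.993550 -10.336389
5.827959 -6.993550 -9.336295
5.827959 -6.993550 -8.336201
5.827959 -6.993550 -7.336107
5.827959 -6.993550 -6.336013
5.827959 -6.993550 -5.335919
5.827959 -6.993550 -4.335825
5.827959 -6.993550 -3.335731
5.827959 -6.993550 -2.335637
5.827959 -6.993550 -1.335543
5.827959 -6.993430 -0.335449
5.827959 -6.980121 0.664470
5.827959 -6.649909 1.607145
5.827959 -5.700367 1.920627
5.827959 -4.700502 1.941982
5.827959 -3.700408 1.942645
5.827959 -2.700314 1.942641
5.827959 -1.700224 1.941556
5.827959 -0.702852 1.883962
5.827959 -0.035507 1.140603
5.827959 -0.000493 0.141125
5.827959 0.000000 -0.858969
5.827959 0.000000 -1.859063
5.827959 0.000000 -2.859157
5.827959 0.000000 -3.859251
5.827959 0.000000 -4.859345
5.827959 -0.000000 -5.859439
5.827959 -0.000000 -6.859533
5.827959 -0.000000 -7.859627
5.827957 -0.000002 -8.859721
5.827804 -0.000186 -9.859815
5.820381 -0.009091 -10.859775
5.680016 -0.177289 -11.835369
5.318746 -0.599275 -12.666951
4.892440 -0.879425 -13.526711
4.456599 -0.656249 -14.398633
4.057325 -0.205603 -15.197185
3.663030 0.266462 -15.985775
3.266132 0.727245 -16.779574
2.826683 0.909415 -17.658849
2.413785 0.555870 -18.498304
2.092280 0.179355 -19.367117
1.957895 0.018290 -20.344925
1.943018 0.000439 -21.344749
1.942653 -0.000001 -22.344842
1.942653 -0.000167 -23.344936
1.942653 -0.016631 -24.344666
1.942653 -0.543946 -25.193300
1.942653 -1.542227 -25.253427
1.942653 -2.542312 -25.251222
1.942653 -3.538022 -25.164800
1.942653 -4.231332 -24.445449
1.942653 -4.273836 -23.446262
1.942653 -4.273836 -22.446168
1.942653 -4.273836 -21.446074
1.942653 -4.273836 -20.445980
1.942653 -4.273836 -19.445886
1.942653 -4.273836 -18.445792
1.942653 -4.273836 -17.445698
1.942653 -4.273836 -16.445604
1.942653 -4.273836 -15.445510
1.942653 -4.273836 -14.445416
1.942653 -4.273836 -13.445322
1.942653 -4.273836 -12.445228
1.942653 -4.273836 -11.445134
1.942653 -4.273836 -10.445040
1.942653 -4.273836 -9.444946
1.942653 -4.273836 -8.444852
1.942653 -4.273836 -7.444758
1.942653 -4.273836 -6.444664
1.942653 -4.273836 -5.444570
1.942653 -4.273836 -4.444476
1.942653 -4.273836 -3.444382
1.942653 -4.273836 -2.444288
1.942653 -4.273836 -1.444194
1.942653 -4.273836 -0.444100
1.942653 -4.273835 0.555994
1.942653 -4.270667 1.555740
1.942653 -3.345531 1.935537
1.942653 -2.345461 1.942495
1.942653 -1.345367 1.942647
1.942653 -0.345471 1.938614
1.942653 0.000000 1.000094
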