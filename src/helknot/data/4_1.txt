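# synthetic closed-curve coordinates for knot 4_1
# generated by helknot's parametric/braid/pretzel builders and
# verified against the Alexander invariant table; columns: x y z (sigma)
2.552440 0.000000 0.000000
2.946501 0.472873 -0.788122
3.340562 0.945747 -1.576244
3.734623 1.418620 -2.364366
4.161329 1.119324 -3.217779
4.557685 0.656141 -4.010490
4.951835 0.183640 -4.798791
5.345899 -0.289223 -5.586918
5.739960 -0.762096 -6.375040
6.134021 -1.234970 -7.163162
6.581110 -1.212120 -8.057341
6.988124 -0.797758 -8.871368
7.383122 -0.328812 -9.661365
7.611581 -0.054880 -10.595590
7.653445 -0.004649 -11.593454
7.657119 -0.000241 -12.593452
7.657313 -0.000008 -13.593466
7.657319 -0.000000 -14.593481
7.463067 0.233102 -15.546332
7.113144 0.653011 -16.383730
6.724627 1.119231 -17.178539
6.280890 1.232980 -18.067434
5.860911 0.889559 -18.907454
5.463786 0.429689 -19.701705
5.189598 0.101632 -20.605704
5.114698 0.011693 -21.598827
5.105514 -0.019854 -22.598301
5.104883 -0.951946 -22.959904
5.104879 -1.951890 -22.971804
5.104879 -2.951905 -22.971957
5.104879 -3.951920 -22.971958
5.104879 -4.951935 -22.971957
5.104879 -5.951950 -22.971688
5.104879 -6.951058 -22.930124
5.104879 -7.376791 -22.025266
5.104879 -7.401147 -21.025547
5.104879 -7.402054 -20.025533
5.104879 -7.402075 -19.025518
5.104879 -7.402075 -18.025503
5.104879 -7.402075 -17.025488
5.104879 -7.402075 -16.025474
5.104879 -7.402075 -15.025459
5.104879 -7.402075 -14.025444
5.104879 -7.402075 -13.025429
5.104879 -7.402075 -12.025414
5.104879 -7.402075 -11.025399
5.104879 -7.402075 -10.025384
5.104879 -7.402075 -9.025369
5.104879 -7.402075 -8.025355
5.104879 -7.402075 -7.025340
5.104879 -7.402075 -6.025325
5.104879 -7.402075 -5.025310
5.104879 -7.402075 -4.025295
5.104879 -7.402075 -3.025280
5.104879 -7.402075 -2.025265
5.104879 -7.402075 -1.025250
5.104879 -7.402075 -0.025236
5.104879 -7.401988 0.974779
5.104879 -7.191352 1.952343
5.104879 -6.331402 2.462305
5.104879 -5.334890 2.545514
5.104879 -4.334898 2.552175
5.104879 -3.334883 2.552436
5.104879 -2.334869 2.552395
5.104879 -1.334932 2.539901
5.104877 -0.371552 2.271758
5.104085 -0.033861 1.330677
5.064178 -0.049847 0.331590
4.787105 -0.381322 -0.570286
4.411460 -0.830152 -1.381133
4.003659 -1.229549 -2.202227
3.559047 -1.123702 -3.091682
3.152204 -0.712966 -3.907649
2.784779 -0.278603 -4.730050
2.596681 -0.053088 -5.685969
2.556455 -0.004818 -6.684007
2.552593 -0.000177 -7.684004
2.552992 0.000659 -8.684018
2.583920 0.037777 -9.682860
2.816159 0.316459 -10.614752
3.175773 0.747024 -11.442593
3.577399 1.162020 -12.258977
4.024336 1.163271 -13.153539
4.438773 0.787486 -13.982426
4.834948 0.323527 -14.774775
5.229081 -0.149044 -15.563042
5.623218 -0.621601 -16.351316
6.024802 -1.061675 -17.154483
6.467081 -1.209725 -18.039043
6.891739 -0.897211 -18.888761
7.277680 -0.454844 -19.698316
7.560311 -0.116407 -20.595851
7.647058 -0.013456 -21.586748
7.657285 -0.150090 -22.577083
7.657319 -1.076290 -22.953969
7.657319 -2.076144 -22.971882
7.657319 -3.076159 -22.971958
7.657319 -4.076174 -22.971958
7.657319 -5.076189 -22.971958
7.657319 -6.076204 -22.971956
7.657319 -7.076218 -22.971631
7.657319 -8.075971 -22.951887
7.657319 -8.991145 -22.549967
7.657319 -9.188783 -21.569699
7.657319 -9.188783 -20.569684
7.657319 -9.188783 -19.569669
7.657319 -9.188783 -18.569654
7.657319 -9.188783 -17.569640
7.657319 -9.188783 -16.569625
7.657319 -9.188783 -15.569610
7.657319 -9.188783 -14.569595
7.657319 -9.188783 -13.569580
7.657319 -9.188783 -12.569565
7.657319 -9.188783 -11.569550
7.657319 -9.188783 -10.569535
7.657319 -9.188783 -9.569521
7.657319 -9.188783 -8.569506
7.657319 -9.188783 -7.569491
7.657319 -9.188783 -6.569476
7.657319 -9.188783 -5.569461
7.657319 -9.188783 -4.569446
7.657319 -9.188783 -3.569431
7.657319 -9.188783 -2.569417
7.657319 -9.188783 -1.569402
7.657319 -9.188771 -0.569387
7.657319 -9.187282 0.430627
7.657319 -9.136796 1.429332
7.657319 -8.641017 2.297659
7.657319 -7.670145 2.537282
7.657319 -6.670244 2.552391
7.657319 -5.670230 2.552440
7.657319 -4.670215 2.552440
7.657319 -3.670200 2.552438
7.657319 -2.670185 2.552313
7.657319 -1.670186 2.546867
7.657319 -0.678194 2.421158
7.657319 -0.080705 1.619341
7.657319 -0.003009 0.622350
7.657319 0.000000 -0.377660
7.657317 0.000003 -1.377675
7.657189 0.000157 -2.377690
7.654253 0.003679 -3.377694
7.620826 0.043789 -4.376339
7.447578 0.251495 -5.339072
7.107614 0.654455 -6.188823
6.707116 1.070409 -7.005277
6.264404 1.211779 -7.890709
5.843293 0.875101 -8.732931
5.447202 0.410787 -9.525114
5.053131 -0.062047 -10.313255
4.658770 -0.533667 -11.101978
4.259819 -0.985568 -11.899881
3.830605 -1.266275 -12.758335
3.400185 -0.997813 -13.620129
3.008218 -0.546920 -14.422056
2.673868 -0.145714 -15.274843
2.562905 -0.012559 -16.259720
2.552458 -0.000021 -17.259602
2.552440 -0.000000 -18.259617
2.552440 -0.000001 -19.259632
2.552440 -0.000095 -20.259646
2.552440 -0.004803 -21.259650
2.552440 -0.118103 -22.253186
2.552440 -0.877581 -22.903651
2.552440 -1.875404 -22.969821
2.552440 -2.875417 -22.971680
2.552440 -3.875400 -22.963797
2.552440 -4.868475 -22.846817
2.552440 -5.587784 -22.152445
2.552440 -5.615367 -21.152811
2.552440 -5.615367 -20.152796
2.552440 -5.615367 -19.152782
2.552440 -5.615367 -18.152767
2.552440 -5.615367 -17.152752
2.552440 -5.615367 -16.152737
2.552440 -5.615367 -15.152722
2.552440 -5.615367 -14.152707
2.552440 -5.615367 -13.152692
2.552440 -5.615367 -12.152677
2.552440 -5.615367 -11.152663
2.552440 -5.615367 -10.152648
2.552440 -5.615367 -9.152633
2.552440 -5.615367 -8.152618
2.552440 -5.615367 -7.152603
2.552440 -5.615367 -6.152588
2.552440 -5.615367 -5.152573
2.552440 -5.615367 -4.152558
2.552440 -5.615367 -3.152544
2.552440 -5.615367 -2.152529
2.552440 -5.615367 -1.152514
2.552440 -5.615366 -0.152499
2.552440 -5.615120 0.847516
2.552440 -5.588997 1.847153
2.552440 -4.841857 2.511788
2.552440 -3.842643 2.551793
2.552440 -2.842628 2.552438
2.552440 -1.842613 2.552245
2.552440 -0.842700 2.538382
2.552440 0.000000 2.000030
2.552440 0.000000 1.000015
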