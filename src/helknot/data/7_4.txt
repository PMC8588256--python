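# synthetic closed-curve coordinates for knot 7_4
# generated by helknot's parametric/braid/pretzel builders and
# verified against the Alexander invariant table; columns: x y z (sigma)
-1.668174 0.000000 0.000000
-1.471677 -0.753623 0.627255
-0.958117 -1.335658 1.257729
-0.238072 -1.621487 1.890060
0.532799 -1.549310 2.522953
1.187046 -1.134307 3.155200
1.568887 -0.460761 3.788079
1.596205 0.311441 4.422870
1.268524 1.009690 5.059325
0.658537 1.480855 5.696444
-0.099822 1.621067 6.333025
-0.836122 1.391249 6.969458
-1.377809 0.843655 7.607202
-1.606452 0.109262 8.246257
-1.472957 -0.647554 8.886109
-1.006837 -1.258918 9.525615
-0.310061 -1.585416 10.164289
0.457379 -1.542976 10.804005
1.117119 -1.150117 11.444635
1.521872 -0.498527 12.086201
1.651907 -0.078679 12.984432
1.669428 -0.005219 13.981578
1.969430 -0.000116 14.935506
2.966484 -0.000001 15.011980
3.966486 -0.000000 15.013554
4.966490 0.000000 15.013347
5.966190 0.000001 14.989259
6.653504 0.000347 14.262917
6.676907 0.016883 13.263325
6.748675 0.256676 12.295166
7.052751 0.962109 11.654930
7.647727 1.447613 11.014390
8.399073 1.605238 10.373581
9.139527 1.399957 9.733589
9.702094 0.875280 9.094655
9.951398 0.146574 8.456814
9.833077 -0.614068 7.818511
9.379547 -1.235527 7.179679
8.691304 -1.580547 6.541487
7.920314 -1.571491 5.904700
7.241215 -1.203821 5.269367
6.813834 -0.560362 4.634301
6.727286 0.206672 3.998557
7.000114 0.929199 3.363324
7.573292 1.448816 2.729712
8.322661 1.647295 2.098008
9.076888 1.466604 1.466747
9.665304 0.963434 0.833830
9.965913 0.269735 0.179298
10.008100 0.010024 -0.785454
10.049853 0.000102 -1.784533
10.746780 0.000000 -2.501650
11.746770 -0.000000 -2.502251
12.746774 -0.000000 -2.501615
13.746567 -0.000004 -2.481096
14.693874 -0.000357 -2.160921
15.014656 -0.007198 -1.213796
15.024791 -0.068605 -0.215733
15.073351 -0.306971 0.754230
15.191879 -0.667419 1.679451
15.388000 -0.991065 2.605084
15.650875 -1.262711 3.530887
15.967936 -1.469322 4.456517
16.324167 -1.599744 5.381772
16.701743 -1.642667 6.306759
17.078766 -1.591408 7.231547
17.432746 -1.453383 8.156563
17.746498 -1.240601 9.081922
18.005181 -0.963428 10.007268
18.196178 -0.635307 10.932397
18.309482 -0.281193 11.860714
18.348045 -0.012979 12.823304
18.349911 -0.000000 13.823222
18.349876 -0.000000 14.823226
18.348045 -0.000000 15.823228
18.295564 -0.000000 16.821845
17.575620 -0.000000 17.515825
16.575617 -0.000000 17.515825
15.575613 -0.000000 17.515825
14.575609 -0.000000 17.515825
13.575606 -0.000000 17.515825
12.575602 0.000000 17.515825
11.575598 0.000000 17.515825
10.575594 0.000000 17.515825
9.575591 0.000000 17.515825
8.575587 0.000000 17.515825
7.575583 0.000000 17.515825
6.575580 0.000000 17.515825
5.575576 0.000000 17.515825
4.575572 0.000000 17.515825
3.575568 0.000000 17.515825
2.575565 0.000000 17.515825
1.575561 0.000000 17.515825
0.575557 0.000000 17.515825
-0.424446 0.000000 17.515796
-1.423811 0.000000 17.481004
-1.668174 0.000000 16.511318
-1.668174 0.000000 15.511314
-1.668174 0.000000 14.511311
-1.668174 0.000000 13.511307
-1.668174 0.000000 12.511303
-1.471677 0.753623 11.884048
-0.958117 1.335658 11.253574
-0.238072 1.621487 10.621243
0.532799 1.549310 9.988350
1.187046 1.134307 9.356104
1.568887 0.460761 8.723224
1.596205 -0.311441 8.088433
1.268524 -1.009690 7.451978
0.658537 -1.480855 6.814859
-0.099822 -1.621067 6.178278
-0.836122 -1.391249 5.541845
-1.377809 -0.843655 4.904101
-1.606452 -0.109262 4.265046
-1.472957 0.647554 3.625194
-1.006837 1.258918 2.985688
-0.310061 1.585416 2.347015
0.457379 1.542976 1.707299
1.117119 1.150117 1.066669
1.521872 0.498527 0.425102
1.651907 0.078679 -0.473129
1.669428 0.005219 -1.470275
1.969430 0.000116 -2.424202
2.966484 0.000001 -2.500677
3.966486 0.000000 -2.502251
4.966490 -0.000000 -2.502044
5.966190 -0.000001 -2.477956
6.653504 -0.000347 -1.751613
6.676907 -0.016883 -0.752022
6.748675 -0.256676 0.216137
7.052751 -0.962109 0.856374
7.647727 -1.447613 1.496913
8.399073 -1.605238 2.137722
9.139527 -1.399957 2.777714
9.702094 -0.875280 3.416648
9.951398 -0.146574 4.054489
9.833077 0.614068 4.692792
9.379547 1.235527 5.331624
8.691304 1.580547 5.969817
7.920314 1.571491 6.606603
7.241215 1.203821 7.241936
6.813834 0.560362 7.877002
6.727286 -0.206672 8.512746
7.000114 -0.929199 9.147979
7.573292 -1.448816 9.781591
8.322661 -1.647295 10.413296
9.076888 -1.466604 11.044556
9.665304 -0.963434 11.677473
9.965913 -0.269735 12.332005
10.008100 -0.010024 13.296757
10.049853 -0.000102 14.295837
10.746780 -0.000000 15.012953
11.746770 0.000000 15.013554
12.746774 0.000000 15.012918
13.746567 0.000004 14.992400
14.693874 0.000357 14.672224
15.014656 0.007198 13.725099
15.024791 0.068605 12.727037
15.073351 0.306971 11.757074
15.191879 0.667419 10.831852
15.388000 0.991065 9.906219
15.650875 1.262711 8.980416
15.967936 1.469322 8.054786
16.324167 1.599744 7.129531
16.701743 1.642667 6.204544
17.078766 1.591408 5.279757
17.432746 1.453383 4.354741
17.746498 1.240601 3.429381
18.005181 0.963428 2.504035
18.196178 0.635307 1.578906
18.309482 0.281193 0.650589
18.348045 0.012979 -0.312001
18.349911 0.000000 -1.311919
18.349876 0.000000 -2.311923
18.348045 0.000000 -3.311925
18.295564 0.000000 -4.310541
17.575620 0.000000 -5.004521
16.575617 0.000000 -5.004521
15.575613 0.000000 -5.004521
14.575609 0.000000 -5.004521
13.575606 0.000000 -5.004521
12.575602 0.000000 -5.004521
11.575598 0.000000 -5.004521
10.575594 0.000000 -5.004521
9.575591 0.000000 -5.004521
8.575587 0.000000 -5.004521
7.575583 0.000000 -5.004521
6.575580 0.000000 -5.004521
5.575576 0.000000 -5.004521
4.575572 0.000000 -5.004521
3.575568 0.000000 -5.004521
2.575565 0.000000 -5.004521
1.575561 0.000000 -5.004521
0.575557 0.000000 -5.004521
-0.424446 0.000000 -5.004493
-1.423811 0.000000 -4.969701
-1.668174 0.000000 -4.000015
-1.668174 0.000000 -3.000011
-1.668174 0.000000 -2.000007
-1.668174 0.000000 -1.000004
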