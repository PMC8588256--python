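# synthetic closed-curve coordinates for knot 6_1
# generated by helknot's parametric/braid/pretzel builders and
# verified against the Alexander invariant table; columns: x y z (sigma)
1.332261 0.000000 0.000000
1.726330 0.472883 -0.788138
2.172527 0.540597 -1.680532
2.547986 0.099129 -2.495484
2.309439 -0.385766 -3.336893
1.883421 -0.561702 -4.224371
1.499560 -0.194657 -5.071698
1.355790 -0.027994 -6.047210
1.343471 -0.013445 -7.047062
1.452745 -0.144580 -8.032419
1.797630 -0.499144 -8.901546
2.228965 -0.420547 -9.800328
2.566741 -0.105834 -10.687420
2.653286 -0.012690 -11.679336
2.689572 0.030098 -12.677796
2.898448 0.275045 -13.624597
3.268989 0.564252 -14.507277
3.694146 0.324324 -15.380019
4.094164 -0.119745 -16.181803
4.500842 -0.534523 -16.995811
4.931615 -0.403885 -17.888792
5.225730 -0.130961 -18.804715
5.318313 -0.402657 -19.762230
5.328850 -1.379882 -19.974215
5.329043 -2.379872 -19.983620
5.329045 -3.379906 -19.983828
5.329045 -4.379881 -19.974675
5.329045 -5.356926 -19.765007
5.329045 -5.701006 -18.826126
5.329045 -5.727478 -17.826443
5.329045 -5.728684 -16.826409
5.329045 -5.728723 -15.826375
5.329045 -5.728724 -14.826340
5.329045 -5.728724 -13.826306
5.329045 -5.728724 -12.826272
5.329045 -5.728724 -11.826237
5.329045 -5.728724 -10.826203
5.329045 -5.728724 -9.826168
5.329045 -5.728724 -8.826134
5.329045 -5.728724 -7.826099
5.329045 -5.728724 -6.826065
5.329045 -5.728724 -5.826031
5.329045 -5.728724 -4.825996
5.329045 -5.728724 -3.825962
5.329045 -5.728724 -2.825927
5.329045 -5.728724 -1.825893
5.329045 -5.728724 -0.825859
5.329045 -5.728724 0.174176
5.329045 -5.202260 1.024222
5.329045 -4.238787 1.292067
5.329045 -3.239419 1.328571
5.329045 -2.239391 1.332003
5.329045 -1.239505 1.318472
5.329045 -0.362945 0.837514
5.329045 -0.044267 -0.110354
5.329045 -0.003065 -1.109539
5.329045 -0.000130 -2.109569
5.329045 -0.000004 -3.109603
5.329045 -0.000000 -4.109638
5.329045 -0.000000 -5.109672
5.329045 -0.000000 -6.109706
5.329045 -0.000000 -7.109741
5.329045 0.000000 -8.109775
5.328352 0.000832 -9.109809
5.256436 0.087131 -10.103511
5.031747 0.354972 -11.040426
4.656889 0.455203 -11.962092
4.237491 0.212171 -12.836747
3.831183 -0.197533 -13.653510
3.397132 -0.408559 -14.529354
2.998551 -0.283265 -15.437871
2.765456 -0.102055 -16.393314
2.683897 -0.021282 -17.386723
2.666890 -0.019185 -18.386605
2.664689 -0.306613 -19.344391
2.664526 -1.153284 -19.876072
2.664523 -2.148540 -19.973479
2.664523 -3.146487 -19.908977
2.664523 -3.723691 -19.092556
2.664523 -3.848612 -18.100375
2.664523 -3.862840 -17.100443
2.664523 -3.863551 -16.100409
2.664523 -3.863558 -15.100375
2.664523 -3.863558 -14.100340
2.664523 -3.863558 -13.100306
2.664523 -3.863558 -12.100272
2.664523 -3.863558 -11.100237
2.664523 -3.863558 -10.100203
2.664523 -3.863558 -9.100168
2.664523 -3.863558 -8.100134
2.664523 -3.863558 -7.100100
2.664523 -3.863558 -6.100065
2.664523 -3.863558 -5.100031
2.664523 -3.863558 -4.099996
2.664523 -3.863558 -3.099962
2.664523 -3.863556 -2.099927
2.664523 -3.863033 -1.099893
2.664523 -3.837230 -0.100193
2.664523 -3.403703 0.800716
2.664336 -2.496187 1.219741
2.660072 -1.496186 1.220977
2.614863 -0.604449 0.770973
2.416080 -0.328426 -0.169394
2.093892 -0.360113 -1.115565
1.778875 -0.214643 -2.053429
1.714118 0.127857 -2.990673
1.993383 0.358561 -3.922742
2.416629 0.336933 -4.828536
2.861222 0.314497 -5.724020
3.297425 0.392903 -6.620466
3.680715 0.288842 -7.538237
3.917810 0.086725 -8.488491
4.016996 -0.023564 -9.477463
4.142922 -0.157923 -10.460390
4.412920 -0.364732 -11.400809
4.798074 -0.432361 -12.321206
5.125826 -0.214999 -13.240661
5.290152 -0.029588 -14.209520
5.275241 0.053634 -15.205974
5.108328 0.214936 -16.178695
4.765523 0.419403 -17.095612
4.374005 0.367115 -18.014319
4.107259 -0.018185 -18.897721
4.002498 -0.638549 -19.675023
3.996851 -1.591736 -19.977177
3.996784 -2.591752 -19.974859
3.996784 -3.587081 -19.877984
3.996784 -4.453130 -19.378275
3.996784 -4.779176 -18.432914
3.996784 -4.796141 -17.433024
3.996784 -4.796141 -16.432989
3.996784 -4.796141 -15.432955
3.996784 -4.796141 -14.432920
3.996784 -4.796141 -13.432886
3.996784 -4.796141 -12.432851
3.996784 -4.796141 -11.432817
3.996784 -4.796141 -10.432783
3.996784 -4.796141 -9.432748
3.996784 -4.796141 -8.432714
3.996784 -4.796141 -7.432679
3.996784 -4.796141 -6.432645
3.996784 -4.796141 -5.432611
3.996784 -4.796141 -4.432576
3.996784 -4.796141 -3.432542
3.996784 -4.796133 -2.432507
3.996784 -4.795720 -1.432473
3.996784 -4.786332 -0.432483
3.996784 -4.672560 0.561048
3.996784 -4.021284 1.319477
3.996784 -3.021613 1.331363
3.996784 -2.021654 1.319039
3.996784 -1.028670 1.200516
3.996784 -0.221293 0.610721
3.996782 -0.000002 -0.364510
3.996746 -0.000045 -1.364545
3.996248 -0.000638 -2.364579
3.991551 -0.006160 -3.364587
3.961488 -0.040456 -4.363581
3.836537 -0.171581 -5.347075
3.527940 -0.415167 -6.266581
3.080964 -0.442566 -7.160732
2.674348 -0.027537 -7.974617
2.265685 0.364130 -8.799032
1.842154 0.477916 -9.697749
1.502432 0.204104 -10.597517
1.332408 0.000175 -11.561646
1.332261 -0.000000 -12.561650
1.332261 -0.000000 -13.561684
1.332261 -0.000000 -14.561719
1.332261 -0.000001 -15.561753
1.332261 -0.000052 -16.561787
1.332261 -0.001422 -17.561821
1.332261 -0.025696 -18.561560
1.332261 -0.294632 -19.524696
1.332261 -1.196084 -19.956230
1.332261 -2.177384 -19.765027
1.332261 -2.844883 -19.020992
1.332261 -2.930975 -18.024677
1.332261 -2.930975 -17.024643
1.332261 -2.930975 -16.024609
1.332261 -2.930975 -15.024574
1.332261 -2.930975 -14.024540
1.332261 -2.930975 -13.024505
1.332261 -2.930975 -12.024471
1.332261 -2.930975 -11.024436
1.332261 -2.930975 -10.024402
1.332261 -2.930975 -9.024368
1.332261 -2.930975 -8.024333
1.332261 -2.930975 -7.024299
1.332261 -2.930975 -6.024264
1.332261 -2.930975 -5.024230
1.332261 -2.930975 -4.024196
1.332261 -2.930975 -3.024161
1.332261 -2.930975 -2.024127
1.332261 -2.930971 -1.024092
1.332261 -2.930534 -0.024058
1.332261 -2.883542 0.974854
1.332261 -1.947456 1.326722
1.332261 -0.947450 1.319727
1.332261 0.000000 1.000034
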