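# synthetic closed-curve coordinates for knot 8_18
# generated by helknot's parametric/braid/pretzel builders and
# verified against the Alexander invariant table; columns: x y z (sigma)
1.576229 0.000000 0.000000
1.970334 0.472926 -0.788209
2.381668 0.865698 -1.610878
2.785981 0.438246 -2.419505
3.180364 -0.033519 -3.208270
3.574474 -0.506420 -3.996490
4.009239 -0.741180 -4.866020
4.422726 -0.360213 -5.692995
4.682040 -0.055730 -6.609660
4.725108 -0.004289 -7.607490
4.728519 -0.000202 -8.607599
4.582257 0.175704 -9.581183
4.236957 0.589220 -10.423742
3.796657 0.633662 -11.320541
3.381869 0.261682 -12.150984
2.985412 -0.201257 -12.943922
2.587333 -0.657233 -13.740081
2.141456 -0.581106 -14.631846
1.749929 -0.198566 -15.468805
1.604576 -0.033466 -16.444359
1.579061 -0.003381 -17.443685
1.587113 0.012631 -18.443649
1.842477 0.319484 -19.360516
2.214744 0.750942 -20.182377
2.650254 0.562395 -21.062375
3.051032 0.119248 -21.864343
3.445621 -0.351635 -22.653531
3.863533 -0.707970 -23.489355
4.298651 -0.480437 -24.360316
4.619532 -0.128918 -25.239905
4.715785 -0.019200 -26.229224
4.728378 -0.880176 -26.736025
4.728683 -1.878592 -26.792898
4.728687 -2.878712 -26.795777
4.728687 -3.878834 -26.793072
4.728687 -4.876454 -26.722369
4.728687 -5.567510 -25.999893
4.728687 -5.669003 -25.005242
4.728687 -5.674309 -24.005138
4.728687 -5.674424 -23.005013
4.728687 -5.674424 -22.004888
4.728687 -5.674424 -21.004762
4.728687 -5.674424 -20.004637
4.728687 -5.674424 -19.004512
4.728687 -5.674424 -18.004386
4.728687 -5.674424 -17.004261
4.728687 -5.674424 -16.004136
4.728687 -5.674424 -15.004010
4.728687 -5.674424 -14.003885
4.728687 -5.674424 -13.003760
4.728687 -5.674424 -12.003634
4.728687 -5.674424 -11.003509
4.728687 -5.674424 -10.003384
4.728687 -5.674424 -9.003258
4.728687 -5.674424 -8.003133
4.728687 -5.674424 -7.003007
4.728687 -5.674424 -6.002882
4.728687 -5.674424 -5.002757
4.728687 -5.674424 -4.002631
4.728687 -5.674424 -3.002506
4.728687 -5.674424 -2.002381
4.728687 -5.674424 -1.002255
4.728687 -5.674424 -0.002130
4.728687 -5.388119 0.955914
4.728687 -4.539373 1.482542
4.728687 -3.543493 1.570006
4.728687 -2.543398 1.576084
4.728687 -1.543272 1.576035
4.728687 -0.559345 1.397124
4.728687 -0.055377 0.534898
4.728674 -0.001125 -0.463417
4.727897 0.000937 -1.463536
4.708673 0.023987 -2.463209
4.510999 0.259088 -3.414856
4.157975 0.626669 -4.275282
3.719067 0.564373 -5.171397
3.307109 0.176042 -5.995612
2.910029 -0.284233 -6.789779
2.499453 -0.679893 -7.611431
2.067103 -0.535208 -8.500916
1.729554 -0.183061 -9.373898
1.596518 -0.023643 -10.352042
1.584724 0.009302 -11.351490
1.656817 0.095548 -12.345257
1.932476 0.389159 -13.260489
2.343957 0.614767 -14.143622
2.779876 0.399509 -15.017108
3.182855 -0.034100 -15.823084
3.589859 -0.448298 -16.637354
4.029426 -0.570351 -17.527120
4.414737 -0.341273 -18.420813
4.642509 -0.102094 -19.364757
4.713208 -0.008656 -20.357872
4.679433 0.057799 -21.355185
4.490058 0.272783 -22.313265
4.142688 0.548009 -23.209738
3.718376 0.513697 -24.114435
3.371875 0.224071 -25.006578
3.199412 -0.142997 -25.920673
3.156029 -0.866933 -26.608571
3.152539 -1.851467 -26.779275
3.152459 -2.851514 -26.784526
3.152458 -3.840587 -26.636645
3.152458 -4.557092 -25.940247
3.152458 -4.570953 -24.941519
3.152458 -4.571063 -23.941394
3.152458 -4.571064 -22.941269
3.152458 -4.571064 -21.941144
3.152458 -4.571064 -20.941018
3.152458 -4.571064 -19.940893
3.152458 -4.571064 -18.940768
3.152458 -4.571064 -17.940642
3.152458 -4.571064 -16.940517
3.152458 -4.571064 -15.940392
3.152458 -4.571064 -14.940266
3.152458 -4.571064 -13.940141
3.152458 -4.571064 -12.940015
3.152458 -4.571064 -11.939890
3.152458 -4.571064 -10.939765
3.152458 -4.571064 -9.939639
3.152458 -4.571064 -8.939514
3.152458 -4.571064 -7.939389
3.152458 -4.571064 -6.939263
3.152458 -4.571064 -5.939138
3.152458 -4.571064 -4.939013
3.152458 -4.571064 -3.938887
3.152458 -4.571064 -2.938762
3.152458 -4.571064 -1.938637
3.152458 -4.571025 -0.938511
3.152458 -4.562970 0.061581
3.152458 -4.414285 1.050520
3.152458 -3.529214 1.509823
3.152458 -2.531344 1.572551
3.152403 -1.531232 1.568911
3.149744 -0.547419 1.389303
3.099651 -0.102224 0.496519
2.892655 -0.297229 -0.462226
2.492556 -0.622568 -1.319075
2.054376 -0.565163 -2.216186
1.721911 -0.174761 -3.074774
1.579013 -0.002982 -4.049582
1.580869 0.005526 -5.049664
1.643588 0.080600 -6.044927
1.907560 0.386889 -6.959648
2.329257 0.698882 -7.810923
2.763679 0.461311 -8.679816
3.158811 -0.007307 -9.470080
3.555144 -0.470733 -10.262763
3.983200 -0.756581 -11.119870
4.391842 -0.398880 -11.959685
4.701903 -0.032072 -12.836698
4.727678 -0.000875 -13.836003
4.723430 0.006252 -14.836081
4.642586 0.101816 -15.828153
4.275929 0.513739 -16.662455
3.843096 0.745508 -17.533345
3.434976 0.336569 -18.349709
3.039528 -0.130707 -19.140607
2.633667 -0.550446 -19.952518
2.192771 -0.666736 -20.842457
1.818794 -0.288894 -21.689551
1.601437 -0.030225 -22.630823
1.576934 -0.000848 -23.630216
1.576237 -0.000239 -24.630341
1.576229 -0.012499 -25.630358
1.576229 -0.332757 -26.576759
1.576229 -1.311304 -26.783080
1.576229 -2.310088 -26.735734
1.576229 -3.186555 -26.256351
1.576229 -3.464966 -25.295917
1.576229 -3.467704 -24.295795
1.576229 -3.467704 -23.295670
1.576229 -3.467704 -22.295545
1.576229 -3.467704 -21.295419
1.576229 -3.467704 -20.295294
1.576229 -3.467704 -19.295169
1.576229 -3.467704 -18.295043
1.576229 -3.467704 -17.294918
1.576229 -3.467704 -16.294793
1.576229 -3.467704 -15.294667
1.576229 -3.467704 -14.294542
1.576229 -3.467704 -13.294416
1.576229 -3.467704 -12.294291
1.576229 -3.467704 -11.294166
1.576229 -3.467704 -10.294040
1.576229 -3.467704 -9.293915
1.576229 -3.467704 -8.293790
1.576229 -3.467704 -7.293664
1.576229 -3.467704 -6.293539
1.576229 -3.467704 -5.293414
1.576229 -3.467704 -4.293288
1.576229 -3.467704 -3.293163
1.576229 -3.467704 -2.293038
1.576229 -3.467701 -1.292912
1.576229 -3.467355 -0.292787
1.576229 -3.443518 0.706985
1.576229 -2.824862 1.492638
1.576229 -1.828022 1.573619
1.576229 -0.828007 1.560956
1.576229 0.000000 1.000125
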