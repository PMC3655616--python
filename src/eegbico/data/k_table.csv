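# Up-down correction values k, indexed by terminal response pattern
# (response before first change, the change, then six responses).
# Generated by eegbico.behavior.build_k_table(): probit ML threshold
# with sigma = 1 ladder step, expressed in steps relative to the last
# filament. Provenance: this package (Dixon-style, not a published table).
pattern,k
OXOOOOOO,-1.2076
OXOOOOOX,-1.9157
OXOOOOXO,-0.2291
OXOOOOXX,-0.7391
OXOOOXOO,-0.5331
OXOOOXOX,-1.0311
OXOOOXXO,0.6781
OXOOOXXX,0.2441
OXOOXOOO,-0.8174
OXOOXOOX,-1.3219
OXOOXOXO,0.4064
OXOOXOXX,-0.0
OXOOXXOO,0.1444
OXOOXXOX,-0.2525
OXOOXXXO,1.5
OXOOXXXX,1.0383
OXOXOOOO,-1.0724
OXOXOOOX,-1.5971
OXOXOOXO,0.1444
OXOXOOXX,-0.2525
OXOXOXOO,-0.1095
OXOXOXOX,-0.5
OXOXOXXO,1.2525
OXOXOXXX,0.8201
OXOXXOOO,-0.3463
OXOXXOOX,-0.7475
OXOXXOXO,1.0
OXOXXOXX,0.584
OXOXXXOO,0.7559
OXOXXXOX,0.3412
OXOXXXXO,2.1017
OXOXXXXX,1.5277
OXXOOOOO,-1.3033
OXXOOOOX,-1.8486
OXXOOOXO,-0.097
OXXOOOXX,-0.5
OXXOOXOO,-0.3463
OXXOOXOX,-0.7475
OXXOOXXO,1.0
OXXOOXXX,0.584
OXXOXOOO,-0.584
OXXOXOOX,-1.0
OXXOXOXO,0.7475
OXXOXOXX,0.3463
OXXOXXOO,0.5
OXXOXXOX,0.097
OXXOXXXO,1.8486
OXXOXXXX,1.3033
OXXXOOOO,-0.8027
OXXXOOOX,-1.2441
OXXXOOXO,0.5
OXXXOOXX,0.097
OXXXOXOO,0.2441
OXXXOXOX,-0.1631
OXXXOXXO,1.5744
OXXXOXXX,1.0554
OXXXXOOO,0.0
OXXXXOOX,-0.4256
OXXXXOXO,1.2922
OXXXXOXX,0.7847
OXXXXXOO,1.0138
OXXXXXOX,0.5038
OXXXXXXO,2.219
OXXXXXXX,1.5016
XOOOOOOO,-1.5016
XOOOOOOX,-2.219
XOOOOOXO,-0.5038
XOOOOOXX,-1.0138
XOOOOXOO,-0.7847
XOOOOXOX,-1.2922
XOOOOXXO,0.4256
XOOOOXXX,0.0
XOOOXOOO,-1.0554
XOOOXOOX,-1.5744
XOOOXOXO,0.1631
XOOOXOXX,-0.2441
XOOOXXOO,-0.097
XOOOXXOX,-0.5
XOOOXXXO,1.2441
XOOOXXXX,0.8027
XOOXOOOO,-1.3033
XOOXOOOX,-1.8486
XOOXOOXO,-0.097
XOOXOOXX,-0.5
XOOXOXOO,-0.3463
XOOXOXOX,-0.7475
XOOXOXXO,1.0
XOOXOXXX,0.584
XOOXXOOO,-0.584
XOOXXOOX,-1.0
XOOXXOXO,0.7475
XOOXXOXX,0.3463
XOOXXXOO,0.5
XOOXXXOX,0.097
XOOXXXXO,1.8486
XOOXXXXX,1.3033
XOXOOOOO,-1.5277
XOXOOOOX,-2.1017
XOXOOOXO,-0.3412
XOXOOOXX,-0.7559
XOXOOXOO,-0.584
XOXOOXOX,-1.0
XOXOOXXO,0.7475
XOXOOXXX,0.3463
XOXOXOOO,-0.8201
XOXOXOOX,-1.2525
XOXOXOXO,0.5
XOXOXOXX,0.1095
XOXOXXOO,0.2525
XOXOXXOX,-0.1444
XOXOXXXO,1.5971
XOXOXXXX,1.0724
XOXXOOOO,-1.0383
XOXXOOOX,-1.5
XOXXOOXO,0.2525
XOXXOOXX,-0.1444
XOXXOXOO,0.0
XOXXOXOX,-0.4064
XOXXOXXO,1.3219
XOXXOXXX,0.8174
XOXXXOOO,-0.2441
XOXXXOOX,-0.6781
XOXXXOXO,1.0311
XOXXXOXX,0.5331
XOXXXXOO,0.7391
XOXXXXOX,0.2291
XOXXXXXO,1.9157
XOXXXXXX,1.2076
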