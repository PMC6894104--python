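32601
32603
32605
32607
32608
32609
32641
32653
34470
34471
45201
45208
45212
45219
45220
45227
45230
45236
45242
45255
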