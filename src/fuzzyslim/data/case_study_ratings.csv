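subtask_id,level,name,rating
1.1,category,personal,5.814
1.1,category,job,4.49
1.1,category,organization,3.593
1.2,category,personal,5.814
1.2,category,job,4.49
1.2,category,organization,4.28
1.3,category,personal,5.814
1.3,category,job,4.49
1.3,category,organization,3.956
1.4,category,personal,6.384
1.4,category,job,4.49
1.4,category,organization,4.604
2.1,category,personal,6.042
2.1,category,job,5.08
2.1,category,organization,4.11
2.2,category,personal,6.156
2.2,category,job,3.925
2.2,category,organization,3.566
2.3,category,personal,5.928
2.3,category,job,3.925
2.3,category,organization,4.324
2.4,category,personal,5.928
2.4,category,job,3.925
2.4,category,organization,3.033
2.5,category,personal,6.27
2.5,category,job,3.925
2.5,category,organization,3.242
2.6,category,personal,5.814
2.6,category,job,4.275
2.6,category,organization,3.132
2.7,category,personal,6.042
2.7,category,job,4.275
2.7,category,organization,3.748
3.1,category,personal,6.498
3.1,category,job,4.888
3.1,category,organization,4.687
3.2,category,personal,6.498
3.2,category,job,4.888
3.2,category,organization,4.687
3.3,category,personal,6.156
3.3,category,job,3.868
3.3,category,organization,3.85
3.4,category,personal,6.27
3.4,category,job,3.868
3.4,category,organization,4.478
3.5,category,personal,6.27
3.5,category,job,4.043
3.5,category,organization,4.181
3.6,category,personal,6.27
3.6,category,job,3.733
3.6,category,organization,4.687
3.7,category,personal,6.384
3.7,category,job,4.138
3.7,category,organization,4.268
4.1,category,personal,6.384
4.1,category,job,4.248
4.1,category,organization,4.269
4.2,category,personal,6.156
4.2,category,job,4.248
4.2,category,organization,4.39
4.3,category,personal,6.384
4.3,category,job,4.248
4.3,category,organization,5.106
4.4,category,personal,6.384
4.4,category,job,4.248
4.4,category,organization,4.897
4.5,category,personal,6.156
4.5,category,job,4.248
4.5,category,organization,3.873
4.6,category,personal,6.042
4.6,category,job,4.248
4.6,category,organization,4.896
4.7,category,personal,6.384
4.7,category,job,3.573
4.7,category,organization,4.896
5.1,category,personal,6.042
5.1,category,job,3.534
5.1,category,organization,4.379
5.2,category,personal,6.042
5.2,category,job,3.669
5.2,category,organization,4.071
5.3,category,personal,6.042
5.3,category,job,3.669
5.3,category,organization,4.197
5.4,category,personal,6.042
5.4,category,job,3.844
5.4,category,organization,4.896
5.5,category,personal,6.042
5.5,category,job,4.019
5.5,category,organization,4.687
5.6,category,personal,6.27
5.6,category,job,3.669
5.6,category,organization,3.43
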