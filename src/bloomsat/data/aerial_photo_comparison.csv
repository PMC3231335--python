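site_id,count_date1,count_date2,count_reference,matched_1_ref,nonflowering_1_ref,matched_2_ref,nonflowering_2_ref
1292,5,7,6,5,0,5,2
1293,8,8,9,7,1,7,1
1294,8,14,9,8,0,9,5
1301,3,6,4,3,0,3,3
1345,3,6,7,3,0,6,0
1352,2,6,8,2,0,6,0
1360,3,5,3,3,0,3,2
1364,7,8,8,7,0,5,3
1371,3,8,7,2,1,6,2
1372,9,13,13,8,1,9,4
1373,6,13,9,3,3,4,9
1378,3,4,7,3,0,3,1
1791,4,6,7,3,1,5,1
1864,2,3,7,1,1,2,1
1881,3,3,9,3,0,3,0
1944,15,11,12,11,4,6,5
1945,10,16,15,10,0,9,7
1956,2,6,6,2,0,6,0
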