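age,infant_age,parity,caesarean,educ_grade12,employed,hiv,nurse_helpful,bses_item_1,bses_item_2,bses_item_3,bses_item_4,bses_item_5,bses_item_6,bses_item_7,bses_item_8,bses_item_9,bses_item_10,bses_item_11,bses_item_12,bses_item_13,bses_item_14,currently_breastfeeding,ever_given_other,hlq_hps_1,hlq_hps_2,hlq_hps_3,hlq_hps_4,hlq_hsi_1,hlq_hsi_2,hlq_hsi_3,hlq_hsi_4,asset_1,asset_2,asset_3,asset_4,asset_5,asset_6,asset_7,asset_8,asset_9,asset_10,asset_11,asset_12,asset_13
23.41966692103526,10.0,1.0,0.0,1.0,1.0,1.0,sometimes,2,3,4,5,4,3,4,5,5,4,5,4,3,4,True,False,4,1,4,4,2,1,1,2,0,0,1,1,0,1,1,0,1,1,0,1,1
37.20154509684419,17.0,4.0,0.0,1.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,3,4,3,4,1,4,1,1,1,0,1,0,0,1,0,0,1,0,1,1,1
28.258077527584177,2.0,1.0,0.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,3,3,3,1,1,4,4,4,0,1,1,1,1,0,1,1,1,1,0,0,1
32.10031225361652,19.0,3.0,1.0,0.0,1.0,0.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,False,True,3,4,3,4,3,4,4,3,1,1,1,1,0,1,0,1,1,0,0,0,1
30.98558877033811,17.0,3.0,0.0,0.0,0.0,0.0,always,5,5,4,5,5,5,4,4,5,5,4,5,5,5,True,False,4,1,4,1,3,1,4,3,1,1,1,0,0,1,1,1,0,0,0,1,0
27.834897173256664,10.0,2.0,1.0,1.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,4,2,1,4,2,1,1,1,0,1,0,1,1,1,0,1,0,1,1,0,1
32.70213371982233,5.0,4.0,0.0,0.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,4,3,3,1,3,3,4,4,0,1,0,1,1,0,0,1,1,1,0,0,1
35.503212673770655,1.0,3.0,0.0,1.0,1.0,0.0,always,2,2,4,5,5,2,3,5,4,5,2,2,4,2,True,False,1,2,1,1,4,1,3,3,0,0,1,1,1,1,0,1,0,1,1,1,1
22.955718028006952,1.0,2.0,1.0,0.0,1.0,1.0,sometimes,2,5,4,3,5,3,3,3,2,4,3,2,3,4,False,True,1,1,4,2,3,4,2,4,1,1,1,1,1,0,1,0,1,0,1,1,1
38.18498237419138,1.0,3.0,0.0,0.0,1.0,0.0,seldom,4,4,5,5,4,4,3,2,4,5,4,5,5,3,True,False,4,2,2,4,1,3,2,4,0,1,1,1,0,1,0,1,1,1,1,1,0
31.107513753759825,3.0,3.0,0.0,1.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,3,2,3,2,2,4,2,1,1,1,1,1,0,1,0,0,0,1,0,1,0
31.79850518879897,8.0,5.0,1.0,0.0,0.0,0.0,sometimes,5,4,5,5,5,5,5,5,5,5,5,5,5,5,True,False,1,4,2,2,4,4,2,2,1,0,1,1,0,1,1,1,1,1,1,1,1
29.19800521657555,17.0,2.0,0.0,1.0,0.0,1.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,1,3,1,4,2,4,1,2,1,0,0,1,0,1,1,0,0,1,1,1,1
28.54720948505464,4.0,1.0,0.0,0.0,0.0,0.0,sometimes,5,4,5,3,5,4,4,5,5,5,4,4,5,5,True,False,1,2,2,4,4,4,2,2,1,1,1,1,0,1,1,1,0,1,0,1,0
35.35813758620577,7.0,2.0,0.0,0.0,0.0,1.0,always,5,4,5,4,5,5,5,3,5,5,5,4,5,5,True,True,2,1,4,2,4,2,1,3,1,1,0,1,1,0,0,1,0,1,1,0,1
27.857164127150895,5.0,1.0,1.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,3,4,2,3,3,3,4,2,0,1,0,1,0,0,1,0,0,0,1,1,1
32.25745305028386,14.0,2.0,0.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,2,1,1,4,4,4,2,4,1,0,0,0,0,1,1,0,0,0,1,0,0
22.797756050672245,1.0,1.0,0.0,0.0,0.0,1.0,sometimes,4,5,5,5,5,5,5,4,4,5,4,5,4,4,False,True,3,4,1,2,4,1,3,3,0,1,1,1,1,1,0,0,0,0,1,1,1
20.160028159187515,6.0,2.0,0.0,1.0,0.0,0.0,sometimes,5,5,4,5,5,5,5,5,5,5,5,5,5,4,True,False,4,4,1,4,3,2,1,3,1,1,1,1,1,0,0,1,1,1,0,0,1
35.95142413565608,4.0,2.0,1.0,1.0,0.0,0.0,always,5,5,5,5,5,5,4,4,4,4,5,5,5,3,True,False,4,3,2,3,2,4,3,1,0,0,1,1,1,0,1,1,1,1,1,1,1
18.828489922178804,1.0,2.0,0.0,1.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,4,1,1,4,4,2,3,1,1,0,1,1,1,0,0,1,0,0,1,1,1
27.19214766331794,12.0,2.0,1.0,1.0,0.0,0.0,always,5,5,5,5,5,5,5,5,4,5,5,5,5,4,True,False,2,2,3,4,3,1,1,3,0,1,1,0,1,1,1,1,0,0,1,1,0
29.373526959871633,3.0,4.0,0.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,4,5,5,5,5,4,5,5,True,False,3,4,4,3,1,2,1,1,1,1,1,0,0,0,1,0,1,1,1,0,0
21.114371347068012,3.0,1.0,1.0,1.0,0.0,1.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,True,2,3,1,4,4,1,2,4,1,1,1,0,1,1,0,1,1,1,1,1,1
25.186911161187616,2.0,1.0,0.0,1.0,1.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,3,2,4,4,1,3,2,2,0,1,0,1,1,0,1,1,1,1,0,1,1
32.02783503975212,7.0,1.0,0.0,0.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,1,1,4,2,2,4,1,3,1,1,1,1,0,0,1,0,1,1,0,1,0
32.50472684642347,2.0,2.0,0.0,0.0,0.0,0.0,sometimes,5,5,4,5,5,4,5,5,5,5,5,4,5,5,True,False,2,2,2,2,2,2,3,4,0,0,1,1,1,0,1,1,1,1,1,1,1
34.90589956179176,7.0,3.0,0.0,0.0,0.0,0.0,always,5,5,5,5,5,2,5,4,4,5,4,5,4,4,True,False,2,2,2,4,1,2,1,2,1,1,1,1,1,1,1,0,1,0,0,1,1
38.539521680973415,10.0,1.0,0.0,0.0,0.0,0.0,seldom,5,5,4,5,5,5,5,4,1,4,4,4,5,5,False,True,4,2,1,3,2,3,3,3,1,1,0,1,1,1,0,0,1,1,1,1,1
33.07611845869625,10.0,2.0,1.0,1.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,1,2,2,4,1,3,2,2,1,1,1,1,0,0,0,1,0,1,1,0,1
31.861575952228,5.0,1.0,0.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,2,2,3,2,1,2,3,3,1,0,1,0,0,1,0,1,1,0,0,0,0
29.733776844224607,9.0,2.0,0.0,0.0,0.0,0.0,sometimes,3,4,4,4,2,4,2,4,4,3,4,4,4,4,True,False,1,2,1,3,3,2,4,1,1,1,0,1,1,1,0,1,0,1,0,1,1
31.9895569396688,13.0,1.0,0.0,1.0,0.0,0.0,sometimes,3,5,4,3,3,2,4,5,3,5,4,4,5,5,True,False,1,1,4,1,2,1,4,2,1,1,1,1,1,1,0,1,0,1,1,1,1
18.305452038267084,8.0,1.0,1.0,1.0,0.0,0.0,sometimes,5,4,5,5,5,5,5,5,5,5,4,4,5,4,True,False,2,4,4,1,1,4,1,3,0,1,1,1,0,0,0,1,0,0,1,1,0
24.02585594772477,8.0,1.0,1.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,4,1,3,4,2,2,2,4,1,1,1,1,0,0,1,1,0,0,1,0,0
20.825456264674827,6.0,1.0,1.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,5,5,4,5,5,5,4,5,True,False,3,3,2,4,2,3,1,3,0,1,1,1,1,1,1,1,0,1,0,0,1
29.30198583560138,3.0,2.0,0.0,1.0,0.0,0.0,sometimes,4,5,5,4,5,4,4,5,5,5,5,5,5,5,True,False,4,1,4,4,4,2,2,3,1,1,1,0,1,1,1,1,1,1,1,1,0
28.16896753991695,2.0,3.0,0.0,1.0,0.0,0.0,sometimes,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,2,2,4,4,4,4,1,1,1,0,1,1,0,1,1,1,0,0,0,1,1
27.00115073141837,1.0,2.0,0.0,1.0,0.0,0.0,sometimes,4,5,5,4,4,5,4,5,4,4,4,3,5,5,True,False,1,4,3,1,4,2,3,2,1,1,1,1,0,0,1,1,0,0,1,1,1
35.41650848014425,5.0,3.0,0.0,1.0,0.0,0.0,always,5,5,5,5,5,5,5,5,5,5,5,5,5,5,True,False,1,1,2,2,1,4,2,4,0,0,1,1,1,1,0,1,1,1,0,1,1
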