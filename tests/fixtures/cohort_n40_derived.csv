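age,infant_age,parity,assets,caesarean,educ_grade12,employed,hiv,hps_high,hsi_high,x_helpful,bses_total,m_bses_high,y_exclusive
23.41966692103526,10.0,1.0,8.0,0.0,1.0,1.0,1.0,1.0,0.0,0,55,0,1
37.20154509684419,17.0,4.0,7.0,0.0,1.0,0.0,0.0,1.0,0.0,1,70,1,1
28.258077527584177,2.0,1.0,9.0,0.0,1.0,0.0,0.0,1.0,1.0,0,70,1,1
32.10031225361652,19.0,3.0,8.0,1.0,0.0,1.0,0.0,1.0,1.0,0,70,1,0
30.98558877033811,17.0,3.0,7.0,0.0,0.0,0.0,0.0,1.0,1.0,1,66,1,1
27.834897173256664,10.0,2.0,8.0,1.0,1.0,0.0,0.0,1.0,0.0,1,70,1,1
32.70213371982233,5.0,4.0,7.0,0.0,0.0,0.0,0.0,1.0,1.0,1,70,1,1
35.503212673770655,1.0,3.0,9.0,0.0,1.0,1.0,0.0,0.0,1.0,1,47,0,1
22.955718028006952,1.0,2.0,10.0,1.0,0.0,1.0,1.0,0.0,1.0,0,46,0,0
38.18498237419138,1.0,3.0,9.0,0.0,0.0,1.0,0.0,1.0,1.0,0,57,1,1
31.107513753759825,3.0,3.0,7.0,0.0,1.0,0.0,0.0,1.0,0.0,1,70,1,1
31.79850518879897,8.0,5.0,11.0,1.0,0.0,0.0,0.0,0.0,1.0,0,69,1,1
29.19800521657555,17.0,2.0,8.0,0.0,1.0,0.0,1.0,0.0,0.0,0,70,1,1
28.54720948505464,4.0,1.0,9.0,0.0,0.0,0.0,0.0,0.0,1.0,0,63,1,1
35.35813758620577,7.0,2.0,8.0,0.0,0.0,0.0,1.0,0.0,1.0,1,65,1,0
27.857164127150895,5.0,1.0,6.0,1.0,1.0,0.0,0.0,1.0,1.0,0,70,1,1
32.25745305028386,14.0,2.0,4.0,0.0,1.0,0.0,0.0,0.0,1.0,0,70,1,1
22.797756050672245,1.0,1.0,8.0,0.0,0.0,0.0,1.0,1.0,1.0,0,64,1,0
20.160028159187515,6.0,2.0,9.0,0.0,1.0,0.0,0.0,1.0,0.0,0,68,1,1
35.95142413565608,4.0,2.0,10.0,1.0,1.0,0.0,0.0,1.0,1.0,1,64,1,1
18.828489922178804,1.0,2.0,8.0,0.0,1.0,0.0,0.0,1.0,1.0,1,70,1,1
27.19214766331794,12.0,2.0,8.0,1.0,1.0,0.0,0.0,1.0,0.0,1,68,1,1
29.373526959871633,3.0,4.0,7.0,0.0,1.0,0.0,0.0,1.0,0.0,0,68,1,1
21.114371347068012,3.0,1.0,11.0,1.0,1.0,0.0,1.0,1.0,1.0,0,70,1,0
25.186911161187616,2.0,1.0,9.0,0.0,1.0,1.0,0.0,1.0,0.0,1,70,1,1
32.02783503975212,7.0,1.0,8.0,0.0,0.0,0.0,0.0,0.0,1.0,1,70,1,1
32.50472684642347,2.0,2.0,10.0,0.0,0.0,0.0,0.0,0.0,1.0,0,67,1,1
34.90589956179176,7.0,3.0,10.0,0.0,0.0,0.0,0.0,1.0,0.0,1,62,1,1
38.539521680973415,10.0,1.0,10.0,0.0,0.0,0.0,0.0,1.0,1.0,0,61,1,0
33.07611845869625,10.0,2.0,8.0,1.0,1.0,0.0,0.0,0.0,0.0,1,70,1,1
31.861575952228,5.0,1.0,5.0,0.0,1.0,0.0,0.0,0.0,0.0,0,70,1,1
29.733776844224607,9.0,2.0,9.0,0.0,0.0,0.0,0.0,0.0,1.0,0,50,0,1
31.9895569396688,13.0,1.0,11.0,0.0,1.0,0.0,0.0,0.0,0.0,0,55,0,1
18.305452038267084,8.0,1.0,6.0,1.0,1.0,0.0,0.0,1.0,0.0,0,66,1,1
24.02585594772477,8.0,1.0,7.0,1.0,1.0,0.0,0.0,1.0,1.0,0,70,1,1
20.825456264674827,6.0,1.0,9.0,1.0,1.0,0.0,0.0,1.0,0.0,0,68,1,1
29.30198583560138,3.0,2.0,11.0,0.0,1.0,0.0,0.0,1.0,1.0,0,66,1,1
28.16896753991695,2.0,3.0,8.0,0.0,1.0,0.0,0.0,1.0,1.0,0,70,1,1
27.00115073141837,1.0,2.0,9.0,0.0,1.0,0.0,0.0,0.0,1.0,0,61,1,1
35.41650848014425,5.0,3.0,9.0,0.0,1.0,0.0,0.0,0.0,1.0,1,70,1,1
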