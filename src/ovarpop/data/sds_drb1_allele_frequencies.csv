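allele,AB,AS,B,H,K,W
Ovar-DRB1*01:01,2.70,4.55,0.00,1.39,0.00,2.63
Ovar-DRB1*01:04,5.41,6.82,6.52,0.69,4.44,3.95
Ovar-DRB1*01:05,1.35,1.14,2.17,2.08,3.33,1.32
Ovar-DRB1*02:01,0.00,0.00,4.35,2.78,3.33,0.00
Ovar-DRB1*03:03,1.35,0.00,10.87,4.17,6.67,1.32
Ovar-DRB1*03:07,0.00,2.27,10.87,3.47,2.22,1.32
Ovar-DRB1*03:08,1.35,0.00,0.00,0.00,0.00,1.32
Ovar-DRB1*03:11,0.00,3.41,0.00,1.39,0.00,0.00
Ovar-DRB1*04:01,1.35,1.14,0.00,0.00,6.67,3.95
Ovar-DRB1*04:02,9.46,5.68,10.87,13.19,10.00,15.79
Ovar-DRB1*05:01,1.35,2.27,2.17,0.00,2.22,0.00
Ovar-DRB1*05:03,9.46,1.14,0.00,2.08,1.11,6.58
Ovar-DRB1*06:03,10.81,18.18,6.52,7.64,12.22,10.53
Ovar-DRB1*07:02,0.00,0.00,0.00,0.69,0.00,0.00
Ovar-DRB1*08:01,0.00,0.00,0.00,2.08,1.11,0.00
Ovar-DRB1*08:02,2.70,0.00,0.00,0.69,0.00,0.00
Ovar-DRB1*08:03,1.35,3.41,0.00,1.39,2.22,1.32
Ovar-DRB1*08:04,0.00,1.14,0.00,0.69,0.00,0.00
Ovar-DRB1*09:02,1.35,0.00,0.00,0.69,3.33,5.26
Ovar-DRB1*10:01,13.51,27.27,6.52,17.36,17.78,7.89
Ovar-DRB1*10:04,2.70,0.00,0.00,0.00,1.11,0.00
Ovar-DRB1*10:06,1.35,0.00,0.00,0.69,1.11,0.00
Ovar-DRB1*10:08,1.35,0.00,2.17,0.00,0.00,0.00
Ovar-DRB1*12:02,5.41,0.00,6.52,2.08,0.00,6.58
Ovar-DRB1*13:01,0.00,0.00,0.00,0.00,0.00,2.63
Ovar-DRB1*13:02,8.11,7.95,6.52,6.94,2.22,11.84
Ovar-DRB1*13:03,6.76,1.14,6.52,4.86,1.11,9.21
Ovar-DRB1*14:02,1.35,0.00,8.70,0.69,1.11,2.63
Ovar-DRB1*14:03,0.00,0.00,0.00,0.00,1.11,0.00
Ovar-DRB1*16:01,4.05,3.41,2.17,2.78,1.11,1.32
Ovar-DRB1*16:05,2.70,0.00,0.00,0.69,0.00,0.00
Ovar-DRB1*16:06,0.00,0.00,0.00,0.69,0.00,0.00
Ovar-DRB1*16:07,0.00,0.00,0.00,0.69,1.11,0.00
Ovar-DRB1*16:08,0.00,0.00,4.35,0.00,1.11,0.00
Ovar-DRB1*17:02,0.00,0.00,2.17,0.00,0.00,0.00
Ovar-DRB1*18:02,0.00,0.00,0.00,0.00,2.22,0.00
Ovar-DRB1*18:03,0.00,1.14,0.00,0.00,2.22,0.00
Ovar-DRB1*19:01,0.00,0.00,0.00,0.69,0.00,0.00
Ovar-DRB1*20:02,0.00,0.00,0.00,3.47,0.00,1.32
Ovar-DRB1*20:03,0.00,0.00,0.00,2.08,2.22,0.00
Ovar-DRB1*21:01,0.00,0.00,0.00,0.69,0.00,0.00
Ovar-DRB1*24:01,0.00,1.14,0.00,0.69,0.00,1.32
Ovar-DRB1*Sudan1,2.70,4.55,0.00,9.03,5.56,0.00
Ovar-DRB1*Sudan2,0.00,1.14,0.00,0.00,0.00,0.00
Ovar-DRB1*Sudan3,0.00,1.14,0.00,0.00,0.00,0.00
Ovar-DRB1*Sudan4,0.00,0.00,0.00,0.69,0.00,0.00
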