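deployment_id,start_datetime,population,sex,age,duration_h,n_dives,n_capture_dives,calf_age,mother_age,searching_h
oo10_260a,2010-09-17 11:25:12,NRKW,F,8,6.50,605,26,,,1.05
oo11_240a,2011-08-28 15:28:04,NRKW,F,9,3.77,363,4,,,1.24
oo09_235a,2009-08-23 14:17:32,NRKW,F,10,2.74,317,8,,,1.83
oo10_256a,2010-09-13 11:03:10,NRKW,F,10,7.13,821,35,,,3.40
oo11_224a,2011-08-12 08:51:17,NRKW,F,10,1.92,225,5,,,0.38
oo09_237c,2009-08-25 12:35:58,NRKW,F,12,0.97,95,2,1,,0.09
oo09_247a,2009-09-04 10:27:05,NRKW,F,15,1.05,123,2,0,,0
oo09_231a,2009-08-19 11:58:16,NRKW,F,16,7.01,539,16,N,,
oo10_265a,2010-09-22 15:31:15,NRKW,F,20,2.78,302,21,N,,2.14
oo11_246a,2011-09-03 12:46:50,NRKW,F,30,3.50,441,18,0,,2.16
oo11_267a,2011-09-24 11:01:53,NRKW,F,36,6.87,622,12,1,,
oo11_248a,2011-09-05 13:10:15,NRKW,M,6,0.35,29,0,,,0
oo11_248b,2011-09-05 13:53:25,NRKW,M,7,2.74,306,0,,,0.39
oo11_244b,2011-09-01 13:03:11,NRKW,M,11,0.77,69,2,,,0
oo09_239a,2009-08-27 11:41:28,NRKW,M,13,2.00,150,2,,29,0.14
oo12_235b,2012-08-22 14:21:59,NRKW,M,16,4.31,471,11,,32,2.70
oo09_245b,2009-09-02 17:51:45,NRKW,M,21,1.31,123,5,,38,0.54
oo09_244a,2009-09-01 15:14:42,NRKW,M,22,3.92,297,19,,41,1.45
oo09_237d,2009-08-25 16:09:04,NRKW,M,23,3.03,320,9,,N,2.06
oo09_236a,2009-08-24 15:37:43,NRKW,M,24,2.18,158,1,,38,0.54
oo09_245a,2009-09-02 13:34:01,NRKW,M,24,5.52,488,16,,N,2.54
oo10_264a,2010-09-21 17:18:03,NRKW,M,24,1.48,125,2,,N,0.11
oo11_244a,2011-09-01 09:24:22,NRKW,M,26,2.69,180,0,,55,0.76
oo09_234a,2009-08-22 15:26:55,NRKW,M,27,3.72,348,7,,N,2.65
oo11_245a,2011-09-02 07:58:13,NRKW,M,28,11.21,859,10,,42,2.05
oo09_243a,2009-08-31 16:21:36,NRKW,M,29,2.80,234,7,,43,0.63
oo11_224b,2011-08-12 16:19:13,NRKW,M,29,0.21,15,1,,54,0.06
oo09_240a,2009-08-28 11:51:51,NRKW,M,32,3.31,341,13,,N,2.24
oo10_261a,2010-09-18 15:14:55,NRKW,M,39,2.91,296,5,,62,2.37
oo09_238a,2009-08-26 07:59:15,NRKW,U,3,11.19,1019,13,,,3.22
oo14_249m,2014-09-06 09:55:10,SRKW,F,5,5.58,567,10,,,1.30
oo12_266m,2012-09-22 10:39:21,SRKW,F,17,2.39,214,10,N,,1.20
oo10_268m,2010-09-25 10:53:31,SRKW,F,19,7.13,629,3,N,,
oo12_267m,2012-09-23 14:56:07,SRKW,F,19,2.29,244,0,3,,1.11
oo14_264m,2014-09-21 11:31:46,SRKW,F,19,0.65,60,2,N,,0.45
oo10_264m,2010-09-21 12:37:09,SRKW,F,20,2.45,217,0,3,,0
oo10_261m,2010-09-18 15:32:45,SRKW,F,24,0.61,36,0,N,,0.16
oo10_267m,2010-09-24 14:34:45,SRKW,F,36,3.77,278,0,1,,
oo12_266n,2012-09-22 13:45:09,SRKW,F,38,0.42,51,0,2,,0.35
oo12_250m,2012-09-06 10:51:13,SRKW,F,41,6.38,595,18,N,,
oo12_260m,2012-09-16 12:24:02,SRKW,M,2,2.67,153,3,,,
oo10_259m,2010-09-16 15:50:54,SRKW,M,6,1.51,196,5,,,
oo10_251m,2010-09-08 14:40:22,SRKW,M,7,0.99,117,3,,,0.46
oo10_265m,2010-09-22 12:15:42,SRKW,M,9,6.04,517,25,,,2.90
oo12_251m,2012-09-07 11:22:21,SRKW,M,11,1.53,145,8,,,0.87
oo14_266m,2014-09-23 10:53:41,SRKW,M,12,4.35,455,13,,29,3.92
oo12_254m,2012-09-10 10:46:44,SRKW,M,16,6.46,574,9,,N,3.73
oo10_257m,2010-09-14 14:00:35,SRKW,M,17,4.22,516,24,,50,
oo10_270m,2010-09-27 12:47:05,SRKW,M,21,1.01,111,5,,50,
oo14_250m,2014-09-07 09:52:25,SRKW,M,21,8.39,822,17,,43,
oo12_261m,2012-09-17 10:11:55,SRKW,M,22,2.02,174,3,,N,0.78
oo14_263m,2014-09-20 11:57:15,SRKW,M,23,6.08,502,11,,N,2.91
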