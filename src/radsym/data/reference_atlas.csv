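patient,side,group,whole_mean_mm,whole_sd_mm,articular_mean_mm,articular_sd_mm
001,l,males_under40,0.47,0.37,0.38,0.24
001,r,males_under40,0.74,0.48,0.43,0.24
002,l,males_under40,1.01,0.66,0.59,0.36
002,r,males_under40,0.55,0.50,0.30,0.18
003,l,males_under40,1.07,0.68,0.83,0.59
003,r,males_under40,1.39,0.75,0.96,0.55
004,l,males_under40,1.40,0.99,1.33,0.95
004,r,males_under40,1.35,0.86,0.95,0.62
005,l,males_under40,0.83,0.65,0.60,0.49
005,r,males_under40,1.00,0.69,0.51,0.35
006,l,males_under40,0.99,0.59,0.66,0.37
006,r,males_under40,1.27,0.67,0.86,0.47
007,l,males_under40,1.02,0.63,0.67,0.32
007,r,males_under40,1.10,0.55,0.77,0.34
008,l,males_under40,0.71,0.43,0.65,0.36
008,r,males_under40,0.56,0.43,0.38,0.25
009,l,males_under40,0.49,0.35,0.38,0.28
009,r,males_under40,0.59,0.39,0.46,0.28
010,l,males_under40,0.69,0.56,0.58,0.40
010,r,males_under40,0.87,0.63,0.63,0.47
011,l,males_over40,2.03,1.20,1.37,0.69
011,r,males_over40,1.97,1.14,1.34,0.69
012,l,males_over40,1.21,0.82,0.89,0.61
012,r,males_over40,0.76,0.53,0.49,0.38
013,l,males_over40,2.08,0.98,1.42,0.61
013,r,males_over40,2.08,0.99,1.49,0.53
014,l,males_over40,0.66,0.50,0.45,0.30
014,r,males_over40,0.86,0.53,0.54,0.28
015,l,males_over40,1.63,0.87,1.33,0.74
015,r,males_over40,1.50,0.94,1.08,0.70
016,l,males_over40,1.33,0.69,0.81,0.51
016,r,males_over40,1.54,0.82,0.88,0.54
017,l,males_over40,1.05,0.72,0.65,0.40
017,r,males_over40,0.86,0.50,0.57,0.33
018,l,males_over40,0.39,0.29,0.29,0.20
018,r,males_over40,0.64,0.48,0.33,0.27
019,l,males_over40,0.52,0.35,0.34,0.23
019,r,males_over40,0.49,0.42,0.43,0.37
020,l,males_over40,1.45,0.93,0.71,0.42
020,r,males_over40,1.45,0.98,0.68,0.37
021,l,females_under40,0.77,0.45,0.56,0.31
021,r,females_under40,0.73,0.47,0.54,0.31
022,l,females_under40,0.54,0.36,0.34,0.22
022,r,females_under40,0.72,0.55,0.51,0.37
023,l,females_under40,0.98,0.73,0.56,0.30
023,r,females_under40,1.14,0.76,0.69,0.41
024,l,females_under40,1.02,0.63,0.76,0.44
024,r,females_under40,0.93,0.56,0.74,0.41
025,l,females_under40,1.38,0.73,0.68,0.39
025,r,females_under40,1.50,0.91,0.71,0.47
026,l,females_under40,0.55,0.44,0.47,0.34
026,r,females_under40,0.68,0.45,0.61,0.32
027,l,females_under40,1.12,0.62,0.62,0.31
027,r,females_under40,1.03,0.70,0.60,0.30
028,l,females_under40,0.94,0.57,0.55,0.29
028,r,females_under40,1.08,0.59,0.72,0.33
029,l,females_under40,0.66,0.38,0.57,0.28
029,r,females_under40,0.92,0.47,0.65,0.26
030,l,females_under40,0.87,0.50,0.68,0.31
030,r,females_under40,1.11,0.70,0.86,0.43
031,l,females_over40,0.89,0.68,0.57,0.41
031,r,females_over40,0.90,0.60,0.52,0.33
032,l,females_over40,0.67,0.50,0.38,0.26
032,r,females_over40,0.71,0.52,0.47,0.30
033,l,females_over40,0.50,0.36,0.32,0.24
033,r,females_over40,0.63,0.43,0.47,0.29
034,l,females_over40,0.73,0.41,0.49,0.29
034,r,females_over40,0.67,0.41,0.45,0.31
035,l,females_over40,0.85,0.48,0.64,0.37
035,r,females_over40,0.83,0.47,0.68,0.37
036,l,females_over40,1.04,0.71,0.53,0.34
036,r,females_over40,0.98,0.78,0.54,0.37
037,l,females_over40,1.03,0.53,0.64,0.46
037,r,females_over40,0.84,0.52,0.50,0.38
038,l,females_over40,0.81,0.59,0.50,0.31
038,r,females_over40,0.92,0.59,0.62,0.31
039,l,females_over40,0.64,0.45,0.40,0.24
039,r,females_over40,0.59,0.47,0.47,0.32
040,l,females_over40,1.56,0.85,0.75,0.49
040,r,females_over40,1.48,0.72,0.76,0.44
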