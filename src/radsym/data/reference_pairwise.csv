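patient,group,whole_mean_mm,whole_sd_mm,articular_mean_mm,articular_sd_mm
001,males_under40,0.58,0.44,0.29,0.21
002,males_under40,0.76,0.51,0.72,0.39
003,males_under40,0.64,0.43,0.60,0.33
004,males_under40,0.75,0.46,0.74,0.36
005,males_under40,0.51,0.33,0.41,0.25
006,males_under40,0.37,0.21,0.34,0.19
007,males_under40,0.44,0.30,0.38,0.21
008,males_under40,0.68,0.46,0.67,0.33
009,males_under40,0.49,0.28,0.40,0.23
010,males_under40,0.43,0.30,0.36,0.21
011,males_over40,0.41,0.31,0.35,0.22
012,males_over40,0.78,0.49,0.70,0.32
013,males_over40,0.55,0.40,0.41,0.22
014,males_over40,0.76,0.54,0.51,0.34
015,males_over40,0.76,0.51,0.72,0.32
016,males_over40,0.44,0.29,0.35,0.20
017,males_over40,0.48,0.29,0.50,0.23
018,males_over40,0.60,0.36,0.51,0.25
019,males_over40,0.37,0.23,0.32,0.21
020,males_over40,0.59,0.48,0.42,0.27
021,females_under40,0.49,0.35,0.46,0.30
022,females_under40,0.55,0.41,0.44,0.31
023,females_under40,0.31,0.27,0.32,0.21
024,females_under40,0.42,0.33,0.27,0.17
025,females_under40,0.58,0.33,0.51,0.26
026,females_under40,0.52,0.37,0.56,0.32
027,females_under40,0.41,0.29,0.42,0.29
028,females_under40,0.30,0.20,0.29,0.19
029,females_under40,0.49,0.35,0.36,0.21
030,females_under40,0.44,0.30,0.35,0.23
031,females_over40,0.62,0.43,0.51,0.27
032,females_over40,0.51,0.37,0.45,0.27
033,females_over40,0.55,0.35,0.45,0.24
034,females_over40,0.65,0.47,0.63,0.37
035,females_over40,0.49,0.34,0.37,0.21
036,females_over40,0.54,0.39,0.52,0.33
037,females_over40,0.40,0.31,0.41,0.28
038,females_over40,0.33,0.21,0.36,0.20
039,females_over40,0.65,0.49,0.34,0.25
040,females_over40,0.41,0.28,0.37,0.20
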