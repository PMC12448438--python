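trial_id,comparison_id,subgroup,treatment_class,n_randomized,hr_os,hr_os_lo,hr_os_hi,hr_pfs,hr_pfs_lo,hr_pfs_hi,shares_control_with
CameL,camel,female,ici_chemo,117,0.57,0.35,0.92,0.62,0.41,0.95,
CameL,camel,male,ici_chemo,295,0.78,0.59,1.03,0.53,0.41,0.68,
CameL,camel,overall,ici_chemo,412,0.72,0.57,0.92,0.55,0.44,0.69,
CameL-sq,camel-sq,female,ici_chemo,30,1.06,0.21,5.26,0.97,0.40,2.34,
CameL-sq,camel-sq,male,ici_chemo,359,0.55,0.40,0.75,0.35,0.27,0.46,
CameL-sq,camel-sq,overall,ici_chemo,389,0.55,0.40,0.75,0.37,0.29,0.47,
CheckMate 017,checkmate-017,female,ici_alone,64,0.67,0.36,1.25,0.71,0.40,1.26,
CheckMate 017,checkmate-017,male,ici_alone,208,0.57,0.41,0.78,0.63,0.46,0.85,
CheckMate 017,checkmate-017,overall,ici_alone,272,0.62,0.48,0.79,0.61,0.47,0.80,
CheckMate 026,checkmate-026,female,ici_alone,162,1.00,0.66,1.53,1.20,0.82,1.74,
CheckMate 026,checkmate-026,male,ici_alone,261,0.98,0.72,1.33,1.14,0.84,1.53,
CheckMate 026,checkmate-026,overall,ici_alone,423,1.02,0.80,1.30,1.15,0.91,1.45,
CheckMate 057,checkmate-057,female,ici_alone,263,0.78,0.58,1.04,1.04,0.80,1.37,
CheckMate 057,checkmate-057,male,ici_alone,319,0.73,0.56,0.96,0.81,0.63,1.04,
CheckMate 057,checkmate-057,overall,ici_alone,582,0.70,0.58,0.83,0.90,0.75,1.08,
CheckMate 078,checkmate-078,female,ici_alone,107,0.78,0.50,1.20,1.08,0.69,1.73,
CheckMate 078,checkmate-078,male,ici_alone,397,0.77,0.61,0.96,0.72,0.57,0.89,
CheckMate 078,checkmate-078,overall,ici_alone,504,0.75,0.61,0.93,0.78,0.64,0.96,
CHOICE-01,choice-01,female,ici_chemo,88,0.61,0.30,1.30,0.58,0.35,1.00,
CHOICE-01,choice-01,male,ici_chemo,377,0.73,0.54,0.98,0.50,0.39,0.64,
CHOICE-01,choice-01,overall,ici_chemo,465,0.69,0.53,0.92,0.49,0.39,0.61,
EMPOWER-Lung 1,empower-lung-1,female,ici_alone,85,0.78,0.43,1.44,0.83,0.49,1.41,
EMPOWER-Lung 1,empower-lung-1,male,ici_alone,480,0.53,0.42,0.67,0.46,0.37,0.57,
EMPOWER-Lung 1,empower-lung-1,overall,ici_alone,565,0.57,0.46,0.71,0.51,0.41,0.62,
EMPOWER-Lung 3,empower-lung-3,female,ici_chemo,75,0.98,0.54,1.78,0.71,0.42,1.20,
EMPOWER-Lung 3,empower-lung-3,male,ici_chemo,391,0.55,0.42,0.71,0.48,0.38,0.62,
EMPOWER-Lung 3,empower-lung-3,overall,ici_chemo,466,0.65,0.51,0.82,0.55,0.44,0.68,
IMpower130,impower130,female,ici_chemo,279,0.66,0.46,0.93,0.59,0.45,0.78,
IMpower130,impower130,male,ici_chemo,400,0.87,0.66,1.15,0.67,0.54,0.85,
IMpower130,impower130,overall,ici_chemo,679,0.79,0.64,0.98,0.64,0.54,0.77,
IMpower131,impower131,female,ici_chemo,126,0.68,0.44,1.04,0.66,0.45,0.97,
IMpower131,impower131,male,ici_chemo,557,0.91,0.75,1.12,0.71,0.59,0.85,
IMpower131,impower131,overall,ici_chemo,683,0.88,0.73,1.05,0.71,0.60,0.85,
IMpower132,impower132,female,ici_chemo,194,0.76,0.54,1.09,0.51,0.36,0.71,
IMpower132,impower132,male,ici_chemo,384,0.93,0.73,1.18,0.64,0.51,0.79,
IMpower132,impower132,overall,ici_chemo,578,0.86,0.71,1.06,0.60,0.49,0.72,
IPSOS,ipsos,female,ici_alone,125,0.86,0.58,1.27,1.04,0.70,1.52,
IPSOS,ipsos,male,ici_alone,328,0.76,0.59,0.98,0.76,0.59,0.97,
IPSOS,ipsos,overall,ici_alone,453,0.78,0.63,0.97,0.87,0.70,1.07,
JAVELIN Lung 100,javelin-lung-100-q2w,female,ici_alone,97,1.10,0.69,1.75,0.94,0.56,1.58,javelin-lung-100-qw
JAVELIN Lung 100,javelin-lung-100-q2w,male,ici_alone,270,0.77,0.58,1.03,0.66,0.48,0.90,javelin-lung-100-qw
JAVELIN Lung 100,javelin-lung-100-q2w,overall,ici_alone,367,0.85,0.67,1.09,0.71,0.54,0.93,javelin-lung-100-qw
JAVELIN Lung 100,javelin-lung-100-qw,female,ici_alone,66,0.85,0.47,1.54,0.89,0.48,1.65,javelin-lung-100-q2w
JAVELIN Lung 100,javelin-lung-100-qw,male,ici_alone,193,0.78,0.55,1.10,0.67,0.46,0.97,javelin-lung-100-q2w
JAVELIN Lung 100,javelin-lung-100-qw,overall,ici_alone,259,0.79,0.59,1.07,0.72,0.52,0.98,javelin-lung-100-q2w
JAVELIN Lung 200,javelin-lung-200,female,ici_alone,162,1.02,0.72,1.45,1.93,1.24,3.01,
JAVELIN Lung 200,javelin-lung-200,male,ici_alone,367,0.82,0.65,1.03,0.77,0.59,1.01,
JAVELIN Lung 200,javelin-lung-200,overall,ici_alone,529,0.87,0.71,1.05,1.01,0.80,1.28,
KEYNOTE-010,keynote-010,female,ici_alone,399,0.66,0.53,0.84,1.02,0.78,1.32,
KEYNOTE-010,keynote-010,male,ici_alone,634,0.71,0.60,0.86,0.78,0.64,0.94,
KEYNOTE-010,keynote-010,overall,ici_alone,1033,0.70,0.61,0.80,0.84,0.73,0.96,
KEYNOTE-024,keynote-024,female,ici_alone,118,0.95,0.56,1.62,0.75,0.46,1.21,
KEYNOTE-024,keynote-024,male,ici_alone,187,0.54,0.36,0.79,0.39,0.26,0.58,
KEYNOTE-024,keynote-024,overall,ici_alone,305,0.62,0.48,0.81,0.50,0.39,0.65,
KEYNOTE-189,keynote-189,female,ici_chemo,253,0.41,0.30,0.56,0.39,0.29,0.52,
KEYNOTE-189,keynote-189,male,ici_chemo,363,0.74,0.56,0.96,0.58,0.46,0.74,
KEYNOTE-189,keynote-189,overall,ici_chemo,616,0.60,0.50,0.72,0.50,0.42,0.60,
KEYNOTE-407,keynote-407,female,ici_chemo,104,0.42,0.22,0.81,0.49,0.30,0.81,
KEYNOTE-407,keynote-407,male,ici_chemo,455,0.69,0.51,0.94,0.58,0.46,0.73,
KEYNOTE-407,keynote-407,overall,ici_chemo,559,0.71,0.59,0.85,0.62,0.52,0.74,
ORIENT-11,orient-11,female,ici_chemo,94,0.99,0.56,1.77,0.60,0.33,1.10,
ORIENT-11,orient-11,male,ici_chemo,303,0.57,0.43,0.77,0.44,0.32,0.61,
ORIENT-11,orient-11,overall,ici_chemo,397,0.65,0.50,0.85,0.48,0.36,0.64,
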