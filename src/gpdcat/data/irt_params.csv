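item_id,n_categories,alpha,t1,t2,t3,t4
GHQ 1,4,1.75,-3.95,3.08,5.75,
GHQ 2,4,1.53,-0.32,1.99,3.63,
GHQ 3,4,1.27,-2.50,3.12,4.81,
GHQ 4,4,1.46,-3.07,3.97,6.08,
GHQ 5,4,1.87,-1.13,1.93,4.11,
GHQ 6,4,2.07,0.04,3.08,4.69,
GHQ 7,4,1.42,-3.15,2.47,4.46,
GHQ 8,4,1.59,-3.36,4.11,6.46,
GHQ 9,4,2.94,0.01,3.17,5.48,
GHQ 10,4,2.31,0.39,2.93,5.07,
GHQ 11,4,3.07,2.03,4.84,6.97,
GHQ 12,4,1.39,-2.60,2.84,4.87,
Aff 1,5,2.01,-3.19,-0.01,1.58,3.80
Aff 2,5,1.58,-1.94,0.32,1.71,3.81
Aff 3,5,1.57,-3.35,-0.29,1.27,3.48
Aff 4,5,1.41,-0.02,1.47,2.56,3.70
Aff 5,5,1.08,-2.35,-0.14,1.33,3.16
Aff 6,5,2.15,0.74,2.49,3.86,5.77
Aff 7,5,0.96,-1.81,0.38,1.60,3.25
Aff 8,5,3.35,1.48,4.03,5.48,8.33
Aff 9,5,1.29,-1.14,1.37,2.57,4.14
Aff 10,5,1.34,0.60,2.06,3.19,4.81
Aff 11,5,1.29,-1.25,1.47,2.58,4.70
Aff 12,5,1.82,1.40,2.79,4.41,6.52
Aff 13,5,0.98,-2.65,-0.83,0.59,2.04
Aff 14,5,2.46,-0.80,1.69,3.12,5.01
Aff 15,5,0.77,-3.84,-1.78,-0.16,1.61
Aff 16,5,1.54,-1.56,1.04,2.48,4.91
Aff 17,5,1.28,-3.02,0.08,1.47,3.67
Aff 18,5,1.67,-0.26,1.90,3.18,4.80
Aff 19,5,1.23,-2.88,0.04,1.60,3.81
Aff 20,5,2.06,-0.09,1.75,3.39,5.62
Aff 21,5,1.85,-3.98,-0.06,1.73,4.74
Aff 22,5,0.92,-3.08,-0.34,0.93,2.91
Aff 23,5,1.11,-2.58,0.41,1.86,3.87
Aff 24,5,1.61,-3.10,0.13,1.88,4.21
Aff 25,5,0.83,-2.65,0.03,1.63,3.27
Aff 26,5,0.80,-1.66,0.86,1.99,3.75
Aff 27,5,1.66,-3.42,-0.26,1.41,3.70
Aff 28,5,1.31,-3.76,-0.44,1.24,3.73
Aff 29,5,0.97,-1.91,1.06,2.46,4.90
Aff 30,5,1.24,-2.08,0.70,1.98,4.04
Aff 31,5,1.87,-0.74,1.69,3.22,5.16
Aff 32,5,3.02,1.63,3.67,5.55,7.84
Aff 33,5,2.32,0.93,3.02,4.58,6.39
Aff 34,5,2.22,1.23,2.98,4.33,6.08
Aff 35,5,1.64,0.31,2.04,2.98,4.89
Aff 36,5,2.59,0.71,2.82,4.62,7.02
Aff 37,5,1.58,-1.67,0.75,2.19,4.24
Aff 38,5,3.00,0.36,2.72,4.30,6.30
Aff 39,5,0.77,-2.03,0.29,1.62,4.07
Aff 40,5,1.49,0.32,2.27,3.56,5.23
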