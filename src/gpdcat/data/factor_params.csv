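item_id,label,instrument,wording,lambda_general,lambda_specific,tau1,tau2,tau3,tau4
GHQ 1,Able to concentrate,GHQ,positive,0.58,0.60,-1.30,1.01,1.89,
GHQ 2,Lost sleep,GHQ,negative,0.67,,-0.14,0.87,1.59,
GHQ 3,Play useful part,GHQ,positive,0.50,0.54,-0.99,1.24,1.91,
GHQ 4,Making decisions,GHQ,positive,0.52,0.61,-1.08,1.40,2.14,
GHQ 5,Under strain,GHQ,negative,0.74,,-0.45,0.76,1.63,
GHQ 6,Overcome difficulties,GHQ,negative,0.77,,0.01,1.15,1.75,
GHQ 7,Enjoy day-to-day activities,GHQ,positive,0.56,0.49,-1.24,0.97,1.75,
GHQ 8,Able to face problems,GHQ,positive,0.50,0.68,-1.06,1.30,2.04,
GHQ 9,Unhappy,GHQ,negative,0.87,,0.00,0.93,1.62,
GHQ 10,Lose confidence,GHQ,negative,0.81,,0.14,1.02,1.77,
GHQ 11,Worthless person,GHQ,negative,0.88,,0.58,1.38,1.98,
GHQ 12,Reasonably happy,GHQ,positive,0.54,0.53,-1.01,1.10,1.89,
Aff 1,Life on the right track,AFF,positive,0.68,0.46,-1.08,0.00,0.53,1.29
Aff 2,Change life,AFF,negative,0.68,,-0.83,0.14,0.74,1.64
Aff 3,Future looks good,AFF,positive,0.60,0.47,-1.27,-0.11,0.48,1.32
Aff 4,Best years are over,AFF,negative,0.64,,-0.01,0.66,1.16,1.67
Aff 5,Like yourself,AFF,positive,0.46,0.50,-1.01,-0.06,0.57,1.36
Aff 6,Something wrong,AFF,negative,0.78,,0.27,0.91,1.41,2.10
Aff 7,Handle problems,AFF,positive,0.45,0.40,-0.85,0.18,0.75,1.53
Aff 8,Failure,AFF,negative,0.89,,0.39,1.07,1.46,2.22
Aff 9,Loved and trusted,AFF,positive,0.51,0.53,-0.45,0.54,1.02,1.64
Aff 10,Left alone,AFF,negative,0.62,,0.28,0.95,1.47,2.22
Aff 11,Close to people,AFF,positive,0.50,0.57,-0.48,0.56,0.99,1.81
Aff 12,Lost interest,AFF,negative,0.73,,0.56,1.12,1.77,2.62
Aff 13,Do whatever want,AFF,positive,0.46,0.37,-1.26,-0.39,0.28,0.97
Aff 14,Life stuck,AFF,negative,0.82,,-0.27,0.56,1.04,1.67
Aff 15,Energy to spare,AFF,positive,0.40,0.27,-1.98,-0.92,-0.08,0.83
Aff 16,Can't be bothered,AFF,negative,0.67,,-0.68,0.46,1.08,2.14
Aff 17,Smiling a lot,AFF,positive,0.56,0.35,-1.33,0.04,0.65,1.62
Aff 18,Nothing fun,AFF,negative,0.70,,-0.11,0.80,1.33,2.01
Aff 19,Thinking creatively,AFF,positive,0.51,0.50,-1.19,0.02,0.66,1.58
Aff 20,Thoughts useless,AFF,negative,0.77,,-0.03,0.65,1.27,2.10
Aff 21,Satisfied,AFF,positive,0.64,0.50,-1.37,-0.02,0.60,1.63
Aff 22,Optimistic,AFF,positive,0.43,0.43,-1.44,-0.16,0.43,1.36
Aff 23,Useful,AFF,positive,0.49,0.45,-1.13,0.18,0.82,1.70
Aff 24,Confident,AFF,positive,0.61,0.47,-1.17,0.05,0.71,1.59
Aff 25,Understood,AFF,positive,0.40,0.41,-1.28,0.01,0.79,1.58
Aff 26,Interested in others,AFF,positive,0.37,0.50,-0.77,0.40,0.92,1.74
Aff 27,Relaxed,AFF,positive,0.66,0.31,-1.37,-0.10,0.56,1.48
Aff 28,Enthusiastic,AFF,positive,0.53,0.50,-1.51,-0.18,0.50,1.50
Aff 29,Good natured,AFF,positive,0.43,0.49,-0.85,0.47,1.09,2.18
Aff 30,Clear headed,AFF,positive,0.51,0.49,-0.86,0.29,0.82,1.67
Aff 31,Discontented,AFF,negative,0.74,,-0.29,0.67,1.27,2.04
Aff 32,Hopeless,AFF,negative,0.87,,0.47,1.06,1.60,2.26
Aff 33,Insignificant,AFF,negative,0.81,,0.32,1.05,1.59,2.22
Aff 34,Helpless,AFF,negative,0.79,,0.44,1.07,1.55,2.18
Aff 35,Lonely,AFF,negative,0.69,,0.13,0.87,1.26,2.07
Aff 36,Withdrawn,AFF,negative,0.84,,0.23,0.91,1.49,2.26
Aff 37,Tense,AFF,negative,0.68,,-0.72,0.32,0.94,1.83
Aff 38,Depressed,AFF,negative,0.87,,0.10,0.79,1.25,1.83
Aff 39,Impatient,AFF,negative,0.41,,-1.09,0.16,0.87,2.18
Aff 40,Confused,AFF,negative,0.66,,0.14,1.00,1.58,2.31
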