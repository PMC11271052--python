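2026-09-28 18:45:11,784 hganlda.synthetic INFO repaired 6 isolated nodes in E_ld
2026-09-28 18:45:11,785 hganlda.synthetic INFO repaired 10 isolated nodes in E_lm
2026-09-28 18:45:11,785 hganlda.synthetic INFO repaired 2 isolated nodes in E_md
2026-09-28 18:45:11,996 hganlda.train_eval INFO fold 1: auc=0.5496 aupr=0.5411 loss=0.6543
2026-09-28 18:45:12,183 hganlda.train_eval INFO fold 2: auc=0.5579 aupr=0.6754 loss=0.6471
2026-09-28 18:45:12,368 hganlda.train_eval INFO fold 3: auc=0.4127 aupr=0.5149 loss=0.5825
2026-09-28 18:45:12,707 hganlda.train_eval INFO fold 1: auc=0.5496 aupr=0.5411 loss=0.6543
2026-09-28 18:45:12,905 hganlda.train_eval INFO fold 2: auc=0.5579 aupr=0.6754 loss=0.6471
2026-09-28 18:45:13,091 hganlda.train_eval INFO fold 3: auc=0.4127 aupr=0.5149 loss=0.5825
2026-09-28 19:25:19,908 hganlda.synthetic INFO repaired 2 isolated nodes in E_lm
2026-09-28 19:25:19,909 hganlda.synthetic INFO repaired 14 isolated nodes in E_ld
2026-09-28 19:25:19,909 hganlda.synthetic INFO repaired 12 isolated nodes in E_lm
2026-09-28 19:25:19,909 hganlda.synthetic INFO repaired 14 isolated nodes in E_md
2026-09-28 19:25:19,910 hganlda.synthetic INFO repaired 1 isolated nodes in E_ld
2026-09-28 19:25:19,910 hganlda.synthetic INFO repaired 5 isolated nodes in E_lm
2026-09-28 19:25:19,910 hganlda.synthetic INFO repaired 4 isolated nodes in E_md
2026-09-28 19:25:19,911 hganlda.synthetic INFO repaired 5 isolated nodes in E_lm
2026-09-28 19:25:19,911 hganlda.synthetic INFO repaired 6 isolated nodes in E_md
2026-09-28 19:25:19,914 hganlda.synthetic INFO repaired 1 isolated nodes in E_ld
2026-09-28 19:25:19,915 hganlda.synthetic INFO repaired 71 isolated nodes in E_lm
2026-09-28 19:25:19,917 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:25:19,918 hganlda.synthetic INFO repaired 8 isolated nodes in E_lm
2026-09-28 19:25:19,918 hganlda.synthetic INFO repaired 5 isolated nodes in E_md
2026-09-28 19:25:19,932 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:25:19,932 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:25:19,932 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:25:19,936 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:25:19,936 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:25:19,936 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:25:19,937 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:25:19,937 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:25:19,937 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:25:19,938 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:25:19,938 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:25:19,938 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:25:20,091 hganlda.train_eval INFO fold 1: auc=0.5496 aupr=0.5411 loss=0.6543
2026-09-28 19:25:20,182 hganlda.train_eval INFO fold 2: auc=0.5579 aupr=0.6754 loss=0.6471
2026-09-28 19:25:20,275 hganlda.train_eval INFO fold 3: auc=0.4127 aupr=0.5149 loss=0.5825
2026-09-28 19:25:20,444 hganlda.train_eval INFO fold 1: auc=0.5496 aupr=0.5411 loss=0.6543
2026-09-28 19:25:20,537 hganlda.train_eval INFO fold 2: auc=0.5579 aupr=0.6754 loss=0.6471
2026-09-28 19:25:20,626 hganlda.train_eval INFO fold 3: auc=0.4127 aupr=0.5149 loss=0.5825
2026-09-28 19:55:48,399 hganlda.synthetic INFO repaired 2 isolated nodes in E_lm
2026-09-28 19:55:48,401 hganlda.synthetic INFO repaired 14 isolated nodes in E_ld
2026-09-28 19:55:48,401 hganlda.synthetic INFO repaired 12 isolated nodes in E_lm
2026-09-28 19:55:48,401 hganlda.synthetic INFO repaired 14 isolated nodes in E_md
2026-09-28 19:55:48,402 hganlda.synthetic INFO repaired 1 isolated nodes in E_ld
2026-09-28 19:55:48,402 hganlda.synthetic INFO repaired 5 isolated nodes in E_lm
2026-09-28 19:55:48,402 hganlda.synthetic INFO repaired 4 isolated nodes in E_md
2026-09-28 19:55:48,402 hganlda.synthetic INFO repaired 5 isolated nodes in E_lm
2026-09-28 19:55:48,402 hganlda.synthetic INFO repaired 6 isolated nodes in E_md
2026-09-28 19:55:48,407 hganlda.synthetic INFO repaired 1 isolated nodes in E_ld
2026-09-28 19:55:48,407 hganlda.synthetic INFO repaired 71 isolated nodes in E_lm
2026-09-28 19:55:48,410 hganlda.synthetic INFO repaired 6 isolated nodes in E_ld
2026-09-28 19:55:48,411 hganlda.synthetic INFO repaired 20 isolated nodes in E_lm
2026-09-28 19:55:48,411 hganlda.synthetic INFO repaired 17 isolated nodes in E_md
2026-09-28 19:55:49,681 hganlda.train_eval INFO fold 1: auc=0.4686 aupr=0.4945 loss=0.4955
2026-09-28 19:55:50,939 hganlda.train_eval INFO fold 2: auc=0.4754 aupr=0.4921 loss=0.4468
2026-09-28 19:55:52,084 hganlda.train_eval INFO fold 3: auc=0.4678 aupr=0.4905 loss=0.4503
2026-09-28 19:55:52,086 hganlda.synthetic INFO repaired 1 isolated nodes in E_lm
2026-09-28 19:55:53,397 hganlda.train_eval INFO fold 1: auc=0.6941 aupr=0.6702 loss=0.4938
2026-09-28 19:55:54,652 hganlda.train_eval INFO fold 2: auc=0.8056 aupr=0.7823 loss=0.3207
2026-09-28 19:55:55,852 hganlda.train_eval INFO fold 3: auc=0.6909 aupr=0.6811 loss=0.3547
2026-09-28 19:55:57,354 hganlda.train_eval INFO fold 1: auc=0.8727 aupr=0.8360 loss=0.3250
2026-09-28 19:55:58,621 hganlda.train_eval INFO fold 2: auc=0.8772 aupr=0.8390 loss=0.3385
2026-09-28 19:55:59,996 hganlda.train_eval INFO fold 3: auc=0.8732 aupr=0.8543 loss=0.3177
2026-09-28 19:55:59,999 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:55:59,999 hganlda.synthetic INFO repaired 8 isolated nodes in E_lm
2026-09-28 19:55:59,999 hganlda.synthetic INFO repaired 5 isolated nodes in E_md
2026-09-28 19:56:00,011 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:56:00,011 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:56:00,011 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:56:00,015 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:56:00,015 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:56:00,015 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:56:00,016 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:56:00,016 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:56:00,016 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:56:00,017 hganlda.synthetic INFO repaired 3 isolated nodes in E_ld
2026-09-28 19:56:00,017 hganlda.synthetic INFO repaired 6 isolated nodes in E_lm
2026-09-28 19:56:00,017 hganlda.synthetic INFO repaired 10 isolated nodes in E_md
2026-09-28 19:56:00,158 hganlda.train_eval INFO fold 1: auc=0.5496 aupr=0.5411 loss=0.6543
2026-09-28 19:56:00,247 hganlda.train_eval INFO fold 2: auc=0.5579 aupr=0.6754 loss=0.6471
2026-09-28 19:56:00,332 hganlda.train_eval INFO fold 3: auc=0.4127 aupr=0.5149 loss=0.5825
2026-09-28 19:56:00,484 hganlda.train_eval INFO fold 1: auc=0.5496 aupr=0.5411 loss=0.6543
2026-09-28 19:56:00,564 hganlda.train_eval INFO fold 2: auc=0.5579 aupr=0.6754 loss=0.6471
2026-09-28 19:56:00,643 hganlda.train_eval INFO fold 3: auc=0.4127 aupr=0.5149 loss=0.5825
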