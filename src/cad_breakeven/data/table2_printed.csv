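scenario,pricing,USA,UK,Poland
concurrent_reader,pay_per_use,4.2 (95% CI: 2.6–5.8),2.7 (95% CI: 1.7–3.8),1.0 (95% CI: 0.6–1.3)
concurrent_reader,one_off_license,12.3 (95% CI: 8.9–20.2),19.0 (95% CI: 13.7–31.1),53.6 (95% CI: 38.6–87.9)
concurrent_reader,yearly_subscription,4.8 (95% CI: 3.4–7.8),7.4 (95% CI: 5.3–12.1),20.8 (95% CI: 15.0–34.0)
prescreen_best_case,pay_per_use,5.4 (95% CI: 3.8–7.1),3.5 (95% CI: 2.4–4.6),1.3 (95% CI: 0.9–1.6)
prescreen_best_case,one_off_license,9.4 (95% CI: 7.2–13.7),14.5 (95% CI: 11.1–21.1),40.8 (95% CI: 31.2–59.6)
prescreen_best_case,yearly_subscription,3.6 (95% CI: 2.8–5.3),5.6 (95% CI: 4.3–8.2),15.8 (95% CI: 12.1–23.1)
prescreen_worst_case,pay_per_use,3.5 (95% CI: 2.3–4.5),2.3 (95% CI: 1.5–2.9),0.8 (95% CI: 0.5–1.0)
prescreen_worst_case,one_off_license,14.9 (95% CI: 11.4–21.8),23.0 (95% CI: 17.6–33.6),65.0 (95% CI: 49.7–94.9)
prescreen_worst_case,yearly_subscription,5.8 (95% CI: 4.4–8.4),8.9 (95% CI: 6.8–13.0),25.2 (95% CI: 19.3–36.8)
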