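id,age,sex,smoking,heart_events_recently,risk
sigma1,74,male,no,yes,medium-risk
sigma2,81,female,no,yes,medium-risk
sigma3,74,male,yes,yes,high-risk
sigma4,71,male,no,yes,high-risk
sigma5,76,female,no,no,low-risk
sigma6,67,male,yes,no,medium-risk
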