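class_label,events,non_events,median
underweight,19,74,17
normal weight,359,1153,23
overweight,642,1275,28
obese,974,1050,35
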