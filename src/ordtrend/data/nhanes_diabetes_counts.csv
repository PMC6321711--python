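class_label,events,non_events,median
underweight,1,92,17
normal weight,105,1406,23
overweight,219,1699,28
obese,460,1563,35
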