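label	substitutions
M1	G8D, K36D, V50D, N62D, Q136E, L238E
M2	N24D, V39D, R57D, Q74E, K169E, N252D
M3	G8D, N24D, K36D, V39D, V50D, R57D, N62D, Q74E, Q136E, K169E, L238E, N252D
M4	G8D, K18E, N24D, K36D, V39D, V50D, R57D, N62D, Q74E, T85D, Q136E, K169E, N177D, N186E, Q220E, L238E, N252D, Q254E
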