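# name	pattern
walker_a	G-XX-[GA]-X-G-K-[ST]
atp_binding	[LIVMFYC]-S-[SGQDEVAHL]-G-X(3)-[RKALV]-[LIVMYATC]-X-[LIVMF]-[AGCT]
walker_b	[ΦHY]-[ΦCY]-[ΦC]-[ΦCT]-[D]-[DEI]
walker_a_classic	G-X(4)-G-K-[ST]
atp_binding_classic	[LIVMFY]-S-[SG]-G-X(3)-[RKA]-[LIVMYA]-X-[LIVMF]-[AG]
walker_b_classic	[Φ](4)-[D]
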