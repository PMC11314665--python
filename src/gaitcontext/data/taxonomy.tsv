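name	category	roles	rationale
Stairs	1	context	Stairs explain higher step-to-step variability and asymmetry
Doorway	1	context	Doorways can provoke freezing of gait in some people with Parkinson's
Shower	1	context	Indicates the type of room
Sink	1	context	Indicates the type of room
Toilet	1	context	Indicates the type of room
Table	1	context	Explains gait variability when manoeuvring; can provoke freezing
Bed	1	context	Indicates the type of room
Signage	1	context	Pausing to read signage explains signal fluctuations
Vehicle	1	context	Indicates the type of environment
Chair	2	context,fall_risk	Possible tripping hazard due to obstruction
Animal	2	context,fall_risk	Animals crossing the walking path are a tripping hazard
Wet surface	2	context,fall_risk	Slippery surface hazard
Matt/rug/carpet	3	fall_risk	Surface-friction change and curled edges are tripping hazards
Obstacle	3	fall_risk	Generic catch-all for obstructions
Raised kerb	3	fall_risk	Tripping hazard
Person	4	context,privacy	Blurred for privacy; navigating around people also alters gait
Screen	4	privacy	Any screen (laptop/TV/phone) is blurred
Book	4	privacy	Catch-all for text documents; blurred
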