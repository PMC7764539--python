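sample	group
150	I
118	I
154	I
170	II
176	II
147	II
124	III
157	III
206	III
200	III
127	IV
177	IV
134	IV
207	Reference
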