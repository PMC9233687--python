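basal-like	synthetic placeholder set for tests, not a published signature	BGENE01	BGENE02	BGENE03	BGENE04	BGENE05	BGENE06	BGENE07	BGENE08	BGENE09	BGENE10
classical	synthetic placeholder set for tests, not a published signature	CGENE01	CGENE02	CGENE03	CGENE04	CGENE05	CGENE06	CGENE07	CGENE08	CGENE09	CGENE10
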