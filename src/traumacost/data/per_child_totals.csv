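perspective,horizon,NoDetention,FamilyDetention,ZeroTolerance
direct,5,23652,24281,24887
societal,5,33008,33790,34544
direct,10,49593,50734,51875
societal,10,74139,75644,77158
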