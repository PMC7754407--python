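perspective,horizon,scenario,cohort,published_incremental
direct,5,FamilyDetention,cohort1,1473118
direct,5,FamilyDetention,cohort2,10560910
direct,5,FamilyDetention,cohort3,14923025
direct,5,ZeroTolerance,cohort1,2892370
direct,5,ZeroTolerance,cohort2,20735650
direct,5,ZeroTolerance,cohort3,29300375
societal,5,FamilyDetention,cohort1,1831440
societal,5,FamilyDetention,cohort2,13129780
societal,5,FamilyDetention,cohort3,18552950
societal,5,ZeroTolerance,cohort1,3597312
societal,5,ZeroTolerance,cohort2,25789440
societal,5,ZeroTolerance,cohort3,36441600
direct,10,FamilyDetention,cohort1,2672222
direct,10,FamilyDetention,cohort2,19157390
direct,10,FamilyDetention,cohort3,27070225
direct,10,ZeroTolerance,cohort1,5344444
direct,10,ZeroTolerance,cohort2,38314780
direct,10,ZeroTolerance,cohort3,54140450
societal,10,FamilyDetention,cohort1,3524710
societal,10,FamilyDetention,cohort2,25268950
societal,10,FamilyDetention,cohort3,35706125
societal,10,ZeroTolerance,cohort1,7070498
societal,10,ZeroTolerance,cohort2,50689010
societal,10,ZeroTolerance,cohort3,71625775
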