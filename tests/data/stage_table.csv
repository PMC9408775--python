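dilution,crests_broken,membranes_ruptured,stage
NONE,False,False,4
NONE,False,True,1
NONE,True,False,2
NONE,True,True,1
SPOTS,False,False,3
SPOTS,False,True,1
SPOTS,True,False,2
SPOTS,True,True,1
WIDESPREAD,False,False,3
WIDESPREAD,False,True,1
WIDESPREAD,True,False,2
WIDESPREAD,True,True,1
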