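problem,probability,index
Force,0.24,32
Interpersonal sensitivity,0.32,25
Depression,0.43,27
Anxiety,0.37,26
Hostile,0.42,36
Phobic paranoid,0.26,18
Psychotic,0.22,22
Sleeping state,0.29,34
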