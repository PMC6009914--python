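descriptor,lower,upper
mw,130.0,725.0
logp,-2.0,6.5
logs,-6.5,0.5
logkp,-8.0,-1.0
logkhsa,-1.5,1.5
logbb,-3.0,1.2
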