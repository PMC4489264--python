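# pairwise weights over atom-type classes; default all-ones (pure surface weighting)
class,c1,c2,c3,c4,c5,c6,c7,c8
c1,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
c2,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
c3,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
c4,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
c5,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
c6,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
c7,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
c8,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0
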