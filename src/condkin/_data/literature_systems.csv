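name,mechanism,n1,n2
Tau,fragmentation,,
Ure2p,fragmentation,,
IAPP,monomer-dependent secondary nucleation,,
Amyloid-beta40,monomer-dependent secondary nucleation,,
Amyloid-beta42,monomer-dependent secondary nucleation,,
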