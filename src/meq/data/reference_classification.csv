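cell_id,on_direction,intensity,duration,onset
L36,Invariant,Eye,Same,Both
L42A1,Hand,Hand,Same,Both
L42A4,Mixed,Hand,Same,Both
L42b,Eye,Same,Same,Both
L45,Hand,Same,Same,Both
L47,Invariant,Same,Same,Both
L52b,Invariant,Same,Eye,Eye
L53,Invariant,Same,Eye,Both
L56,Mixed,Same,Same,Eye
L61,Intermediate,Same,Same,Eye
L62,Intermediate,Same,Same,Both
L63,Hand,Same,Eye,Hand
L76,Hand,Same,Mixed,Both
L78,Invariant,Same,Same,Both
L79,Invariant,Eye,Eye,Both
L81,Hand,Same,Same,Eye
L83,Invariant,Same,Eye,Eye
L84,Intermediate,Eye,Same,Both
L87,Invariant,Same,Same,Both
L88b,Hand,Same,Hand,Eye
L89,Invariant,Same,Same,Both
L91,Invariant,Same,Eye,Both
L94,Intermediate,Hand,Same,Eye
L96,Invariant,Same,Intermediate,Both
L97,Eye,Eye,Same,Hand
L98,Invariant,Same,Mixed,Both
L100,Invariant,Same,Same,Eye
R2,Invariant,Same,Same,Both
R37,Invariant,Same,Same,Both
R50,Invariant,Same,Same,Both
R62,Eye,Hand,Hand,Both
R202,Mixed,Same,Eye,Eye
R204,Intermediate,Intermediate,Hand,Eye
R211,Eye,Eye,Eye,Both
R216,Mixed,Same,Mixed,Both
R222,Invariant,Same,Eye,Both
R224,Intermediate,Hand,Same,Both
R233,Hand,Same,Same,Hand
R234,Eye,Same,Same,Both
R238,Hand,Same,Same,Eye
R239,Invariant,Same,Same,Eye
R244,Eye,Same,Intermediate,Both
R248,Invariant,Hand,Same,Both
R249,Invariant,Hand,Same,Both
R250,Invariant,Same,Eye,Both
R251,Invariant,Hand,Invariant,Both
R333,Eye,Same,Intermediate,Both
R337,Invariant,Eye,Eye,Both
R338,Eye,Same,Same,Eye
340,Eye,Same,Eye,Eye
R352,Eye,Same,Same,Both
R353,Invariant,Same,Hand,Both
R354,Invariant,Same,Hand,Eye
R357,Invariant,Same,Same,Both
R358,Invariant,Same,Same,Hand
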