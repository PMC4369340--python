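species,locomotion,burrowing,abbreviation,n_specimens
Romerolagus,saltatorial,yes,Ro,7
Bunolagus,saltatorial,yes,Bu,2
Caprolagus,generalized,yes,Ca,2
Brachylagus,generalized,yes,Br,10
Sylvilagus floridanus,saltatorial,no,Sfl,10
Sylvilagus palustris,generalized,no,Spal,10
Sylvilagus audobonii,saltatorial,yes,Sau,10
Poelagus marjorita,saltatorial,no,Po,10
Pronolagus crossicaudatus,saltatorial,no,Pc,10
Oryctolagus cuninculus,saltatorial,yes,Oc,10
Nesolagus timminsi,saltatorial,yes,Nt,2
Lepus americanus,saltatorial,no,Lam,10
Lepus timidus,saltatorial,yes,Lti,10
Lepus capensis,cursorial,yes,Lcap,10
Lepus californicus,cursorial,no,Lcal,12
Lepus saxatilis,cursorial,no,Lsax,9
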