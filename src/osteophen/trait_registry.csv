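name,units,length_scale
body_mass,g,whole-body
BMC,mg,whole-body
FBG,mg/dL,whole-body
Tt.Ar,mm^2,whole-bone
Ct.Ar,mm^2,whole-bone
Ma.Ar,mm^2,whole-bone
Ct.Th,mm,whole-bone
pMOI,mm^4,whole-bone
TMD,mgHA/cm^3,tissue
K,N/mm,whole-bone
Fu,N,whole-bone
Fy,N,whole-bone
PYD,mm,whole-bone
work,mJ,whole-bone
Su,MPa,tissue
Sy,MPa,tissue
E,MPa,tissue
Lc.NDensity,1/mm^3,lacunar
Lc.Vol/TV,%,lacunar
V.Vol/TV,%,lacunar
Lc.Vol,um^3,lacunar
Lc.AspectRatio,,lacunar
Lc.Sphericity,,lacunar
Lc.MaxFeret,um,lacunar
Lc.Vol/SA,um,lacunar
Lc.SD.Phi,deg,lacunar
Raman.v1.proline,,tissue
Raman.v2.amideIII,,tissue
Raman.carb.phos,,tissue
Raman.crystallinity,1/cm,tissue
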