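formula,putative_name,application,printed_abundance_pct
C20H26O4,dicyclohexyl phthalate,Hardener/plasticizer,0.18
C14H20O2,2.6-di-tertbutyl-p-benzoquinone,Breakdown product,0.01
C10H14O2,2-tert-butylhydroquinone,Rubber filler,0.02
C10H14O2,4-tert-butylpyrocatechol,Solvent/adhesive,0.02
C18H24O6,butoxycarbonylmethyl butyl phthalate,Plasticizer,0.05
C13H10O5,2.2'.4.4'-tetrahydroxybenzophenone,Antioxidant,0.01
C8H8O3,methyl 4-hydroxybenzoate,Antistatic/softener,0.01
C18H18O5,oxydiethylene dibenzoate,Plasticizer/softener,0.01
C8H6O4,isophthalic acid,Lubricant/adhesive,0.17
C14H12O3,oxybenzone,Stabilizer/lubricant,0.01
C18H26O4,dipentyl phthalate,Plasticizer,0.04
C11H16O2,tert-butyl-4-methoxyphenol,Antioxidant,0.02
C17H24O3,7.9-di-tert-butyl-1-oxaspiro(4.5)deca-6.9-diene-2.8-dione,Breakdown product,0.03
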