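fragment_id,role,group_id,variant,structure,n_attachments,provenance
GAL,core,GAL,,[*:1]N1CC[C@]23C=C[C@@H](O)C[C@@H]2Oc2c(OC)ccc(C1)c23,1,explicit
L1,linker,L,,[*:1]CCCCC[*:2],2,placeholder
L2,linker,L,,[*:1]CCCCCC[*:2],2,placeholder
L3,linker,L,,[*:1]CCCCCCC[*:2],2,placeholder
L4,linker,L,,[*:1]CCOCC[*:2],2,placeholder
L5,linker,L,,[*:1]CCNCC[*:2],2,placeholder
L6,linker,L,,[*:1]CCOCCC[*:2],2,placeholder
L7,linker,L,,[*:1]CCNCCC[*:2],2,placeholder
L8,linker,L,,[*:1]CCC(=O)CC[*:2],2,placeholder
L9,linker,L,,[*:1]CCCOCC[*:2],2,placeholder
L10,linker,L,,[*:1]CCNC(=O)CC[*:2],2,explicit
L11,linker,L,,[*:1]CCCNCC[*:2],2,placeholder
L12,linker,L,,[*:1]CCOCCCC[*:2],2,placeholder
L13,linker,L,,[*:1]CCNCCCC[*:2],2,placeholder
L14,linker,L,,[*:1]CCCCOC[*:2],2,placeholder
L15,linker,L,,[*:1]CCCCNC[*:2],2,placeholder
L16,linker,L,,[*:1]CCC(C)CC[*:2],2,placeholder
L17,linker,L,,[*:1]CCCC(C)C[*:2],2,placeholder
L18,linker,L,,[*:1]CC(C)CCC[*:2],2,placeholder
Ar1a,aromatic,Ar1,a,[*:1]c1ccccc1-c1ccccc1,1,explicit
Ar1b,aromatic,Ar1,b,[*:1]COC,1,placeholder
Ar1c,aromatic,Ar1,c,[*:1]COCC,1,placeholder
Ar1d,aromatic,Ar1,d,[*:1]COCCC,1,placeholder
Ar1e,aromatic,Ar1,e,[*:1]COCCCC,1,placeholder
Ar1f,aromatic,Ar1,f,[*:1]COCCCCC,1,placeholder
Ar1g,aromatic,Ar1,g,[*:1]COCCCCCC,1,placeholder
Ar1h,aromatic,Ar1,h,[*:1]COCCCCCCC,1,placeholder
Ar1i,aromatic,Ar1,i,[*:1]COCCCCCCCC,1,placeholder
Ar1j,aromatic,Ar1,j,[*:1]COCCCCCCCCC,1,placeholder
Ar1k,aromatic,Ar1,k,[*:1]COCCCCCCCCCC,1,placeholder
Ar1l,aromatic,Ar1,l,[*:1]COCCCCCCCCCCC,1,placeholder
Ar1m,aromatic,Ar1,m,[*:1]COCCCCCCCCCCCC,1,placeholder
Ar1n,aromatic,Ar1,n,[*:1]COCCCCCCCCCCCCC,1,placeholder
Ar1o,aromatic,Ar1,o,[*:1]COCCCCCCCCCCCCCC,1,placeholder
Ar1p,aromatic,Ar1,p,[*:1]COCCCCCCCCCCCCCCC,1,placeholder
Ar2a,aromatic,Ar2,a,[*:1]N1C=CC=CC1=O,1,explicit
Ar2b,aromatic,Ar2,b,[*:1]CCOC,1,placeholder
Ar2c,aromatic,Ar2,c,[*:1]CCOCC,1,placeholder
Ar2d,aromatic,Ar2,d,[*:1]CCOCCC,1,placeholder
Ar2e,aromatic,Ar2,e,[*:1]CCOCCCC,1,placeholder
Ar2f,aromatic,Ar2,f,[*:1]CCOCCCCC,1,placeholder
Ar2g,aromatic,Ar2,g,[*:1]CCOCCCCCC,1,placeholder
Ar2h,aromatic,Ar2,h,[*:1]CCOCCCCCCC,1,placeholder
Ar2i,aromatic,Ar2,i,[*:1]CCOCCCCCCCC,1,placeholder
Ar2j,aromatic,Ar2,j,[*:1]CCOCCCCCCCCC,1,placeholder
Ar2k,aromatic,Ar2,k,[*:1]CCOCCCCCCCCCC,1,placeholder
Ar2l,aromatic,Ar2,l,[*:1]CCOCCCCCCCCCCC,1,placeholder
Ar2m,aromatic,Ar2,m,[*:1]CCOCCCCCCCCCCCC,1,placeholder
Ar2n,aromatic,Ar2,n,[*:1]CCOCCCCCCCCCCCCC,1,placeholder
Ar2o,aromatic,Ar2,o,[*:1]CCOCCCCCCCCCCCCCC,1,placeholder
Ar2p,aromatic,Ar2,p,[*:1]CCOCCCCCCCCCCCCCCC,1,placeholder
Ar2q,aromatic,Ar2,q,[*:1]CCOCCCCCCCCCCCCCCCC,1,placeholder
Ar2r,aromatic,Ar2,r,[*:1]CCOCCCCCCCCCCCCCCCCC,1,placeholder
Ar2s,aromatic,Ar2,s,[*:1]CCOCCCCCCCCCCCCCCCCCC,1,placeholder
Ar2t,aromatic,Ar2,t,[*:1]CCOCCCCCCCCCCCCCCCCCCC,1,placeholder
Ar2u,aromatic,Ar2,u,[*:1]CCOCCCCCCCCCCCCCCCCCCCC,1,placeholder
Ar2v,aromatic,Ar2,v,[*:1]CCOCCCCCCCCCCCCCCCCCCCCC,1,placeholder
Ar3a,aromatic,Ar3,a,[*:1]c1ccc2[nH]ccc2c1,1,explicit
Ar3b,aromatic,Ar3,b,[*:1]CCCOC,1,placeholder
Ar3c,aromatic,Ar3,c,[*:1]CCCOCC,1,placeholder
Ar3d,aromatic,Ar3,d,[*:1]CCCOCCC,1,placeholder
Ar3e,aromatic,Ar3,e,[*:1]CCCOCCCC,1,placeholder
Ar3f,aromatic,Ar3,f,[*:1]CCCOCCCCC,1,placeholder
Ar3g,aromatic,Ar3,g,[*:1]CCCOCCCCCC,1,placeholder
Ar3h,aromatic,Ar3,h,[*:1]CCCOCCCCCCC,1,placeholder
Ar3i,aromatic,Ar3,i,[*:1]CCCOCCCCCCCC,1,placeholder
Ar4a,aromatic,Ar4,a,[*:1]c1nc2ccccc2[nH]1,1,explicit
Ar4b,aromatic,Ar4,b,[*:1]CCCCOC,1,placeholder
Ar4c,aromatic,Ar4,c,[*:1]CCCCOCC,1,placeholder
Ar4d,aromatic,Ar4,d,[*:1]CCCCOCCC,1,placeholder
Ar4e,aromatic,Ar4,e,[*:1]CCCCOCCCC,1,placeholder
Ar4f,aromatic,Ar4,f,[*:1]CCCCOCCCCC,1,placeholder
Ar4g,aromatic,Ar4,g,[*:1]CCCCOCCCCCC,1,placeholder
Ar4h,aromatic,Ar4,h,[*:1]CCCCOCCCCCCC,1,placeholder
Ar4i,aromatic,Ar4,i,[*:1]CCCCOCCCCCCCC,1,placeholder
Ar4j,aromatic,Ar4,j,[*:1]CCCCOCCCCCCCCC,1,placeholder
Ar4k,aromatic,Ar4,k,[*:1]CCCCOCCCCCCCCCC,1,placeholder
Ar4l,aromatic,Ar4,l,[*:1]CCCCOCCCCCCCCCCC,1,placeholder
Ar4m,aromatic,Ar4,m,[*:1]CCCCOCCCCCCCCCCCC,1,placeholder
Ar4n,aromatic,Ar4,n,[*:1]CCCCOCCCCCCCCCCCCC,1,placeholder
Ar4o,aromatic,Ar4,o,[*:1]CCCCOCCCCCCCCCCCCCC,1,placeholder
Ar5a,aromatic,Ar5,a,[*:1]N1N=C(c2ccccc2)C=CC1=O,1,explicit
Ar5b,aromatic,Ar5,b,[*:1]CCCCCOC,1,placeholder
Ar6a,aromatic,Ar6,a,CC(C)n1cc([*:1])c2ccccc21,1,explicit
Ar6b,aromatic,Ar6,b,[*:1]CCCCCCOC,1,placeholder
Ar7a,aromatic,Ar7,a,[*:1]c1ccc2ccccc2n1,1,explicit
Ar7b,aromatic,Ar7,b,[*:1]CCCCCCCOC,1,placeholder
Ar7c,aromatic,Ar7,c,[*:1]CCCCCCCOCC,1,placeholder
Ar8a,aromatic,Ar8,a,Cn1c([*:1])cc(-c2ccccc2)n1,1,explicit
Ar8b,aromatic,Ar8,b,[*:1]CCCCCCCCOC,1,placeholder
Ar8c,aromatic,Ar8,c,[*:1]CCCCCCCCOCC,1,placeholder
Ar8d,aromatic,Ar8,d,[*:1]CCCCCCCCOCCC,1,placeholder
Ar8e,aromatic,Ar8,e,[*:1]CCCCCCCCOCCCC,1,placeholder
Ar8f,aromatic,Ar8,f,[*:1]CCCCCCCCOCCCCC,1,placeholder
Ar8g,aromatic,Ar8,g,[*:1]CCCCCCCCOCCCCCC,1,placeholder
Ar8h,aromatic,Ar8,h,[*:1]CCCCCCCCOCCCCCCC,1,placeholder
Ar8i,aromatic,Ar8,i,[*:1]CCCCCCCCOCCCCCCCC,1,placeholder
Ar8j,aromatic,Ar8,j,[*:1]CCCCCCCCOCCCCCCCCC,1,placeholder
Ar8k,aromatic,Ar8,k,[*:1]CCCCCCCCOCCCCCCCCCC,1,placeholder
Ar8l,aromatic,Ar8,l,[*:1]CCCCCCCCOCCCCCCCCCCC,1,placeholder
Ar8m,aromatic,Ar8,m,[*:1]CCCCCCCCOCCCCCCCCCCCC,1,placeholder
Ar8n,aromatic,Ar8,n,[*:1]CCCCCCCCOCCCCCCCCCCCCC,1,placeholder
Ar9a,aromatic,Ar9,a,[*:1]c1ccc2ncccc2c1,1,explicit
Ar9b,aromatic,Ar9,b,[*:1]CCCCCCCCCOC,1,placeholder
Ar9c,aromatic,Ar9,c,[*:1]CCCCCCCCCOCC,1,placeholder
Ar9d,aromatic,Ar9,d,[*:1]CCCCCCCCCOCCC,1,placeholder
Ar9e,aromatic,Ar9,e,[*:1]CCCCCCCCCOCCCC,1,placeholder
Ar9f,aromatic,Ar9,f,[*:1]CCCCCCCCCOCCCCC,1,placeholder
Ar9g,aromatic,Ar9,g,[*:1]CCCCCCCCCOCCCCCC,1,placeholder
Ar9h,aromatic,Ar9,h,[*:1]CCCCCCCCCOCCCCCCC,1,placeholder
Ar9i,aromatic,Ar9,i,[*:1]CCCCCCCCCOCCCCCCCC,1,placeholder
Ar9j,aromatic,Ar9,j,[*:1]CCCCCCCCCOCCCCCCCCC,1,placeholder
Ar9k,aromatic,Ar9,k,[*:1]CCCCCCCCCOCCCCCCCCCC,1,placeholder
Ar9l,aromatic,Ar9,l,[*:1]CCCCCCCCCOCCCCCCCCCCC,1,placeholder
Ar9m,aromatic,Ar9,m,[*:1]CCCCCCCCCOCCCCCCCCCCCC,1,placeholder
Ar9n,aromatic,Ar9,n,[*:1]CCCCCCCCCOCCCCCCCCCCCCC,1,placeholder
Ar9o,aromatic,Ar9,o,[*:1]CCCCCCCCCOCCCCCCCCCCCCCC,1,placeholder
Ar9p,aromatic,Ar9,p,[*:1]CCCCCCCCCOCCCCCCCCCCCCCCC,1,placeholder
Ar9q,aromatic,Ar9,q,[*:1]CCCCCCCCCOCCCCCCCCCCCCCCCC,1,placeholder
Ar10a,aromatic,Ar10,a,[*:1]c1ccccc1,1,explicit
Ar10b,aromatic,Ar10,b,[*:1]CCCCCCCCCCOC,1,placeholder
Ar10c,aromatic,Ar10,c,[*:1]CCCCCCCCCCOCC,1,placeholder
Ar10d,aromatic,Ar10,d,[*:1]CCCCCCCCCCOCCC,1,placeholder
Ar10e,aromatic,Ar10,e,[*:1]CCCCCCCCCCOCCCC,1,placeholder
Ar10f,aromatic,Ar10,f,[*:1]CCCCCCCCCCOCCCCC,1,placeholder
Ar10g,aromatic,Ar10,g,[*:1]CCCCCCCCCCOCCCCCC,1,placeholder
Ar10h,aromatic,Ar10,h,[*:1]CCCCCCCCCCOCCCCCCC,1,placeholder
Ar10i,aromatic,Ar10,i,[*:1]CCCCCCCCCCOCCCCCCCC,1,placeholder
Ar10j,aromatic,Ar10,j,[*:1]CCCCCCCCCCOCCCCCCCCC,1,placeholder
Ar10k,aromatic,Ar10,k,[*:1]CCCCCCCCCCOCCCCCCCCCC,1,placeholder
Ar10l,aromatic,Ar10,l,[*:1]CCCCCCCCCCOCCCCCCCCCCC,1,placeholder
Ar10m,aromatic,Ar10,m,[*:1]CCCCCCCCCCOCCCCCCCCCCCC,1,placeholder
Ar11a,aromatic,Ar11,a,[*:1]N1C(=O)Nc2ccccc2C1=O,1,explicit
Ar11b,aromatic,Ar11,b,[*:1]CCCCCCCCCCCOC,1,placeholder
Ar12a,aromatic,Ar12,a,[*:1]N1C(=O)NC(=O)c2ccccc21,1,explicit
Ar13a,aromatic,Ar13,a,[*:1]N1CCCc2ccccc21,1,explicit
Ar14a,aromatic,Ar14,a,[*:1]N1CCc2ccccc2C1,1,explicit
Ar15a,aromatic,Ar15,a,[*:1]C1NCCc2ccccc21,1,explicit
Ar16a,aromatic,Ar16,a,[*:1]c1nccc2ccccc21,1,explicit
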