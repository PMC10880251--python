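salt_id,smiles,class,name
SS-0001,[Na+],counterion,sodium
SS-0002,[K+],counterion,potassium
SS-0003,[Li+],counterion,lithium
SS-0004,[Cs+],counterion,cesium
SS-0005,[Ca+2],counterion,calcium
SS-0006,[Mg+2],counterion,magnesium
SS-0007,[Ba+2],counterion,barium
SS-0008,[Sr+2],counterion,strontium
SS-0009,[Zn+2],counterion,zinc
SS-0010,[Al+3],counterion,aluminium
SS-0011,[Fe+2],counterion,iron(II)
SS-0012,[Fe+3],counterion,iron(III)
SS-0013,[Cu+2],counterion,copper(II)
SS-0014,[Mn+2],counterion,manganese(II)
SS-0015,[Ag+],counterion,silver
SS-0016,[NH4+],counterion,ammonium
SS-0017,[Cl-],counterion,chloride
SS-0018,[Br-],counterion,bromide
SS-0019,[I-],counterion,iodide
SS-0020,[F-],counterion,fluoride
SS-0022,[O-]S([O-])(=O)=O,salt,sulfate
SS-0023,OS([O-])(=O)=O,salt,hydrogensulfate
SS-0024,[O-][N+]([O-])=O,salt,nitrate
SS-0025,[O-]P([O-])([O-])=O,salt,phosphate
SS-0026,OP(O)([O-])=O,salt,dihydrogenphosphate
SS-0027,[O-]C([O-])=O,salt,carbonate
SS-0028,OC([O-])=O,salt,bicarbonate
SS-0029,[O-]Cl(=O)(=O)=O,salt,perchlorate
SS-0030,[B-](F)(F)(F)F,salt,tetrafluoroborate
SS-0031,F[P-](F)(F)(F)(F)F,salt,hexafluorophosphate
SS-0032,CC([O-])=O,salt,acetate
SS-0033,[O-]C=O,salt,formate
SS-0034,[O-]C(=O)C([O-])=O,salt,oxalate
SS-0035,OC(CC([O-])=O)(CC([O-])=O)C([O-])=O,salt,citrate
SS-0036,OC(C(O)C([O-])=O)C([O-])=O,salt,tartrate
SS-0037,[O-]C(=O)/C=C\C([O-])=O,salt,maleate
SS-0038,[O-]C(=O)/C=C/C([O-])=O,salt,fumarate
SS-0039,[O-]C(=O)CCC([O-])=O,salt,succinate
SS-0040,[O-]C(=O)c1ccccc1,salt,benzoate
SS-0041,Oc1ccccc1C([O-])=O,salt,salicylate
SS-0042,CC(O)C([O-])=O,salt,lactate
SS-0043,CS([O-])(=O)=O,salt,methanesulfonate
SS-0044,Cc1ccc(cc1)S([O-])(=O)=O,salt,p-toluenesulfonate
SS-0045,[O-]S(=O)(=O)c1ccccc1,salt,benzenesulfonate
SS-0046,FC(F)(F)C([O-])=O,salt,trifluoroacetate
SS-0049,O,solvent,water
SS-0050,CO,solvent,methanol
SS-0051,CC(C)O,solvent,2-propanol
SS-0052,CC(C)=O,solvent,acetone
SS-0053,CS(C)=O,solvent,dimethyl sulfoxide
SS-0054,CN(C)C=O,solvent,N;N-dimethylformamide
SS-0055,CC#N,solvent,acetonitrile
SS-0056,CCOCC,solvent,diethyl ether
SS-0057,C1CCOC1,solvent,tetrahydrofuran
SS-0058,CCOC(C)=O,solvent,ethyl acetate
SS-0059,ClCCl,solvent,dichloromethane
SS-0060,ClC(Cl)Cl,solvent,chloroform
SS-0061,Cc1ccccc1,solvent,toluene
SS-0062,CCCCCC,solvent,n-hexane
SS-0063,N,solvent,ammonia
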