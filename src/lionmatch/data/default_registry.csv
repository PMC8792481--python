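id,name,countries,mtdna,nudna,certainty,suture_zone,hybrid_origin,managed_metapopulation,extant,notes
sn-niokolo,Niokolo-Koba,SN,West,West,fairly_high,,false,false,true,
wap,W-Arly-Pendjari complex,BF|BJ|NE,West,West,high,,false,false,true,transboundary
ng-kainji,Kainji Lake,NG,West,West,medium,,false,false,true,west Nigeria
ng-yankari,Yankari,NG,Central,Central,medium,,false,false,true,east Nigeria
cm-waza,Waza and Benoue complex,CM,Central,Central,fairly_high,,false,false,true,
td-zakouma,Greater Zakouma-Chinko,CF|TD,Central,Central,fairly_high,,false,false,true,transboundary
cd-garamba,Garamba,CD,Central,Central,medium,,false,false,true,north-east DRC
sz1-horn,Sudan-South Sudan-Ethiopia suture,ET|SD|SS,Central|North East,Central|East,medium,SZ1,false,false,true,natural suture zone 1; two subspecies co-occur
so-arid,Somali arid lands,SO,North East,East,medium,,false,false,true,
ke-north,North Kenya,KE,North East,East,fairly_high,,false,false,true,
ke-south,South Kenya,KE,East/Southern,East,high,,false,false,true,
ke-nakuru,Lake Nakuru-Soysambu,KE,East/Southern|North East,East,high,,true,false,true,founders from Aberdares introduced North East haplotypes
ug-nile,Uganda,UG,North East,East,medium,,false,false,true,
tz-mara,Tanzania-Serengeti-Selous,TZ,East/Southern,East,high,,false,false,true,
cd-east,East DRC,CD,East/Southern,East,medium,,false,false,true,alternative DRC release region
zm-luangwa,Zambia-Luangwa-Kafue,ZM,East/Southern,East|Southern,fairly_high,SZ2,false,false,true,natural suture zone 2
mw-restored,Malawi restored populations,MW,East/Southern|South West,East|Southern,fairly_high,SZ2,true,false,true,restocked from the RSA managed metapopulation
mz-niassa,Mozambique-Niassa-Limpopo,MZ,East/Southern,East|Southern,fairly_high,SZ2,false,false,true,natural suture zone 2
rw-akagera,Akagera,RW,East/Southern|South West,East,medium,,true,false,true,restocked from the RSA managed metapopulation
kaza,Kavango-Zambezi overlap,BW|ZM|ZW,East/Southern|South West,Southern,fairly_high,,false,false,true,natural mtDNA haplogroup overlap; not a suture zone
na-etosha,Etosha,NA,South West,Southern,high,,false,false,true,
ao-south,Angola,AO,South West,Southern,medium,,false,false,true,
kgalagadi,Kgalagadi Transfrontier,BW|ZA,South West,Southern,high,,false,false,true,transboundary
za-kruger,Greater Kruger,ZA,East/Southern|South West,Southern,high,,true,false,true,South West haplotype introgressed via Etosha founders
za-metapop,RSA managed metapopulation,ZA,East/Southern|South West,Southern,high,,true,true,true,small fenced reserves; mixed East/Southern and South West stock
zw-lowveld,Zimbabwe south-east lowveld,ZW,East/Southern|South West,Southern,fairly_high,,true,false,true,partly stocked from RSA
sz-hlane,Hlane Royal,SZ,East/Southern|South West,Southern,medium,,true,false,true,restocked from RSA
ga-bateke,Bateke Plateau,GA,South West,Southern,medium,,false,false,true,haplotype affinity to South West; augmentation planned accordingly
in-gir,Gir Forest,IN,India,India,high,,false,false,true,strongly differentiated Indian population
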