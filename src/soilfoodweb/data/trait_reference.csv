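genus,guild,cp,body_mass
Protorhabditis,Ba,1,0.33
Rhabditis,Ba,1,2.33
Panagrolaimus,Ba,1,0.68
Mesorhabditis,Ba,1,0.70
Diploscapter,Ba,1,0.42
Cephalobus,Ba,2,0.54
Eucephalobus,Ba,2,0.62
Acrobeles,Ba,2,0.72
Acrobeloides,Ba,2,0.36
Plectus,Ba,2,0.80
Chiloplacus,Ba,2,0.84
Prismatolaimus,Ba,3,0.44
Teratocephalus,Ba,3,0.23
Alaimus,Ba,4,0.26
Aphelenchus,Fu,2,0.53
Aphelenchoides,Fu,2,0.18
Filenchus,Fu,2,0.23
Ditylenchus,Fu,2,0.41
Tylencholaimus,Fu,4,0.52
Leptonchus,Fu,4,0.50
Helicotylenchus,Pp,3,0.83
Pratylenchus,Pp,3,0.30
Tylenchorhynchus,Pp,3,0.58
Meloidogyne,Pp,3,0.29
Paratylenchus,Pp,2,0.12
Criconemoides,Pp,3,0.62
Hoplolaimus,Pp,3,2.95
Eudorylaimus,Om,4,1.76
Mesodorylaimus,Om,4,1.05
Aporcelaimellus,Om,5,5.46
Microdorylaimus,Om,4,0.41
Thonus,Om,4,1.00
Mononchus,Ca,4,4.42
Mylonchulus,Ca,4,1.39
Prionchulus,Ca,4,4.20
Clarkus,Ca,4,2.67
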