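alias,canonical_name
Fortunian,Terreneuvian
Cambrian Stage 2,Terreneuvian
Series 2,Cambrian Series 2
Cambrian Stage 3,Cambrian Series 2
Cambrian Stage 4,Cambrian Series 2
Cambrian Series 3,Miaolingian
Series 3,Miaolingian
Cambrian Stage 5,Miaolingian
Wuliuan,Miaolingian
Drumian,Miaolingian
Guzhangian,Miaolingian
Paibian,Furongian
Jiangshanian,Furongian
Cambrian Stage 10,Furongian
Tremadocian,Early Ordovician
Floian,Early Ordovician
Dapingian,Middle Ordovician
Darriwilian,Middle Ordovician
Sandbian,Late Ordovician
Katian,Late Ordovician
Hirnantian,Late Ordovician
Llandoverian,Llandovery
Rhuddanian,Llandovery
Aeronian,Llandovery
Telychian,Llandovery
Wenlockian,Wenlock
Sheinwoodian,Wenlock
Homerian,Wenlock
Ludlovian,Ludlow
Gorstian,Ludlow
Ludfordian,Ludlow
Pridolian,Pridoli
Lochkovian,Early Devonian
Pragian,Early Devonian
Emsian,Early Devonian
Eifelian,Middle Devonian
Givetian,Middle Devonian
Frasnian,Late Devonian
Famennian,Late Devonian
Tournaisian,Early Mississippian
Visean,Middle Mississippian
Serpukhovian,Late Mississippian
Bashkirian,Early Pennsylvanian
Moscovian,Middle Pennsylvanian
Kasimovian,Late Pennsylvanian
Gzhelian,Late Pennsylvanian
Early Permian,Cisuralian
Asselian,Cisuralian
Sakmarian,Cisuralian
Artinskian,Cisuralian
Kungurian,Cisuralian
Middle Permian,Guadalupian
Roadian,Guadalupian
Wordian,Guadalupian
Capitanian,Guadalupian
Late Permian,Lopingian
Wuchiapingian,Lopingian
Changhsingian,Lopingian
Scythian,Early Triassic
Induan,Early Triassic
Olenekian,Early Triassic
Anisian,Middle Triassic
Ladinian,Middle Triassic
Carnian,Late Triassic
Norian,Late Triassic
Rhaetian,Late Triassic
Lias,Early Jurassic
Hettangian,Early Jurassic
Sinemurian,Early Jurassic
Pliensbachian,Early Jurassic
Toarcian,Early Jurassic
Dogger,Middle Jurassic
Aalenian,Middle Jurassic
Bajocian,Middle Jurassic
Bathonian,Middle Jurassic
Callovian,Middle Jurassic
Malm,Late Jurassic
Oxfordian,Late Jurassic
Kimmeridgian,Late Jurassic
Tithonian,Late Jurassic
Berriasian,Early Cretaceous
Valanginian,Early Cretaceous
Hauterivian,Early Cretaceous
Barremian,Early Cretaceous
Aptian,Early Cretaceous
Albian,Early Cretaceous
Cenomanian,Late Cretaceous
Turonian,Late Cretaceous
Coniacian,Late Cretaceous
Santonian,Late Cretaceous
Campanian,Late Cretaceous
Maastrichtian,Late Cretaceous
Palaeocene,Paleocene
Danian,Paleocene
Selandian,Paleocene
Thanetian,Paleocene
Ypresian,Eocene
Lutetian,Eocene
Bartonian,Eocene
Priabonian,Eocene
Rupelian,Oligocene
Chattian,Oligocene
Aquitanian,Miocene
Burdigalian,Miocene
Langhian,Miocene
Serravallian,Miocene
Tortonian,Miocene
Messinian,Miocene
Zanclean,Pliocene
Piacenzian,Pliocene
Gelasian,Pleistocene
Calabrian,Pleistocene
Recent,Holocene
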