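name,era,period,base_ma,top_ma
Terreneuvian,Palaeozoic,Cambrian,541.0,521.0
Cambrian Series 2,Palaeozoic,Cambrian,521.0,509.0
Miaolingian,Palaeozoic,Cambrian,509.0,497.0
Furongian,Palaeozoic,Cambrian,497.0,485.4
Early Ordovician,Palaeozoic,Ordovician,485.4,470.0
Middle Ordovician,Palaeozoic,Ordovician,470.0,458.4
Late Ordovician,Palaeozoic,Ordovician,458.4,443.8
Llandovery,Palaeozoic,Silurian,443.8,433.4
Wenlock,Palaeozoic,Silurian,433.4,427.4
Ludlow,Palaeozoic,Silurian,427.4,423.0
Pridoli,Palaeozoic,Silurian,423.0,419.2
Early Devonian,Palaeozoic,Devonian,419.2,393.3
Middle Devonian,Palaeozoic,Devonian,393.3,382.7
Late Devonian,Palaeozoic,Devonian,382.7,358.9
Early Mississippian,Palaeozoic,Carboniferous,358.9,346.7
Middle Mississippian,Palaeozoic,Carboniferous,346.7,330.9
Late Mississippian,Palaeozoic,Carboniferous,330.9,323.2
Early Pennsylvanian,Palaeozoic,Carboniferous,323.2,315.2
Middle Pennsylvanian,Palaeozoic,Carboniferous,315.2,307.0
Late Pennsylvanian,Palaeozoic,Carboniferous,307.0,298.9
Cisuralian,Palaeozoic,Permian,298.9,272.3
Guadalupian,Palaeozoic,Permian,272.3,259.8
Lopingian,Palaeozoic,Permian,259.8,251.902
Early Triassic,Mesozoic,Triassic,251.902,247.2
Middle Triassic,Mesozoic,Triassic,247.2,237.0
Late Triassic,Mesozoic,Triassic,237.0,201.3
Early Jurassic,Mesozoic,Jurassic,201.3,174.1
Middle Jurassic,Mesozoic,Jurassic,174.1,163.5
Late Jurassic,Mesozoic,Jurassic,163.5,145.0
Early Cretaceous,Mesozoic,Cretaceous,145.0,100.5
Late Cretaceous,Mesozoic,Cretaceous,100.5,66.0
Paleocene,Cenozoic,Paleogene,66.0,56.0
Eocene,Cenozoic,Paleogene,56.0,33.9
Oligocene,Cenozoic,Paleogene,33.9,23.03
Miocene,Cenozoic,Neogene,23.03,5.333
Pliocene,Cenozoic,Neogene,5.333,2.588
Pleistocene,Cenozoic,Quaternary,2.588,0.0117
Holocene,Cenozoic,Quaternary,0.0117,0.0
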