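# Synthetic surname pool (one name per line).
# Invented mix of southern-African family names for testing; not drawn from
# any real register.
Baloyi
Bila
Chabalala
Chauke
Dlamini
Dube
Hlongwane
Hlungwani
Khoza
Khumalo
Kubayi
Mabasa
Mabunda
Madonsela
Mahlangu
Makhubela
Malapane
Maluleke
Manganyi
Mangena
Maritz
Mashaba
Mashele
Masinga
Mathebula
Mathonsi
Mavasa
Mazibuko
Mbhalati
Mdluli
Mhlanga
Mhlongo
Mkhabela
Mkhari
Mnisi
Mokoena
Molefe
Mondlane
Moyane
Mpenyana
Msimango
Mthembu
Mthombeni
Mukansi
Mushwana
Ndlovu
Ngobeni
Ngomane
Ngoveni
Ngwenya
Nhlapo
Nkosi
Nkuna
Novela
Ntimane
Ntuli
Nxumalo
Nyathi
Phakula
Rikhotso
Risenga
Shabangu
Shirinda
Sibuyi
Sithole
Sambo
Tshabalala
Ubisi
Valoyi
Vukeya
Xaba
Zitha
Zulu
Zwane
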