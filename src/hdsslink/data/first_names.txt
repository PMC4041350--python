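# Synthetic first-name pool (one name per line).
# A mix of English and southern-African given names used to emulate a rural
# South African population register; the pool is invented for testing and
# does not reproduce any real population's name distribution.
Amukelani
Andries
Anna
Basani
Beauty
Bongani
Brenda
Busisiwe
Caroline
Clement
Constance
Daniel
David
Dingane
Dumisani
Elias
Elizabeth
Emmanuel
Esther
Eunice
Evelyn
Ezekiel
Faith
Fikile
Florence
Freddy
George
Gezani
Gift
Gladys
Grace
Happy
Hlengiwe
Hope
Irene
Jabulani
Jacob
James
Janet
Jeanette
Johannes
John
Joseph
Joyce
Judith
Julia
Katekani
Khazamula
Khensani
Kenneth
Kulani
Lindiwe
Lucas
Lucky
Lungile
Mandla
Margaret
Martha
Mary
Maria
Mavis
Mbhazima
Mduduzi
Memory
Mikateko
Miriam
Mthavini
Musa
Nkateko
Nomsa
Nonhlanhla
Norman
Ntombi
Nyiko
Patience
Patrick
Paulina
Peter
Philemon
Phindile
Precious
Pretty
Princess
Prudence
Rhandzu
Richard
Risuna
Robert
Rirhandzu
Salphina
Samuel
Sarah
Sibongile
Simon
Sipho
Solly
Surprise
Thandi
Themba
Thomas
Tintswalo
Tsakani
Vusi
William
Winnie
Xongile
Yvonne
Zanele
Zodwa
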