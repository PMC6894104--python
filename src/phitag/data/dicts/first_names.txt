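Alice
Amara
Boris
Brian
Celeste
Clara
Daniel
Dmitri
Elena
Esme
Farid
Frank
Grace
Gwen
Henry
Hiro
Ines
Irene
Jacob
Jonas
Karen
Katya
Leif
Louis
Maria
Mirela
Nadia
Nathan
Olivia
Omar
Peter
Priya
Quinn
Rachel
Rohan
Samuel
Saskia
Teresa
Tomas
Ursula
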