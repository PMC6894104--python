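Alachua
Archer
Brookhaven
Eastvale
Fairmont
Gainesville
Harborview
Hawthorne
Lakeside
Maplewood
Micanopy
Newberry
Northfield
Ocala
Palatka
Silverton
Starke
Stonegate
Waldo
Westbrook
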