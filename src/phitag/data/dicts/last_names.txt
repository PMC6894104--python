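Albright
Anderson
Baxter
Beaumont
Caldwell
Castellano
Dawson
Delacroix
Eastwood
Ellison
Fairbanks
Foster
Goldberg
Granger
Hathaway
Holloway
Ingram
Iverson
Jennings
Jorgensen
Keller
Kowalski
Lawson
Lindqvist
Mercer
Moreau
Norwood
Novak
Okafor
Osborne
Petrov
Prescott
Quimby
Quintana
Redding
Rosenberg
Sheldon
Silverman
Takahashi
Thornton
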