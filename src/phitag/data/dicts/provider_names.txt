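Alice Anderson
Amara Albright
Boris Beaumont
Brian Baxter
Celeste Castellano
Clara Caldwell
Daniel Dawson
Dmitri Delacroix
Elena Ellison
Esme Eastwood
Farid Fairbanks
Frank Foster
Grace Granger
Gwen Goldberg
Henry Holloway
Hiro Hathaway
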