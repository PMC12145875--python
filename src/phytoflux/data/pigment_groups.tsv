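# Default mapping of photosynthetic lineages to the six pigment-based
# phytoplankton groups (plus the explicit other_photo fallback).
# Rules are applied top-down; the first matching rule wins, so class-level
# rules precede division-level fallbacks (e.g. Dictyochophyceae matches
# before the generic Ochrophyta rule; Rappemonadea does not match the
# Prymnesiophyceae rule and falls through to other_photo).
rank	name	group
class	Bacillariophyta	diatoms
class	Dinophyceae	dinoflagellates
class	Prymnesiophyceae	hacrobia
class	Cryptophyceae	hacrobia
class	Dictyochophyceae	dictyo_pelago
class	Pelagophyceae	dictyo_pelago
division	Dinoflagellata	dinoflagellates
division	Cryptophyta	hacrobia
division	Chlorophyta	chlorophytes
division	Ochrophyta	other_ochrophyta
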