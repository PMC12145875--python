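# Default trophic assignment rules for PR2 v4 lineages.
# Matching is by exact name at the stated rank.  Parasite rules always win;
# dinoflagellates are treated as photosynthetic (their trophic strategies are
# variable) unless a parasite rule matches; photosynthetic rules win over
# heterotrophic ones (e.g. Chlorarachniophyceae within Cercozoa).
rank	name	label
class	Syndiniales	parasitic
order	Syndiniales	parasitic
class	Bacillariophyta	photosynthetic
class	Prymnesiophyceae	photosynthetic
class	Cryptophyceae	photosynthetic
class	Pelagophyceae	photosynthetic
class	Dictyochophyceae	photosynthetic
class	Chrysophyceae	photosynthetic
class	Bolidophyceae	photosynthetic
class	Raphidophyceae	photosynthetic
class	Pinguiophyceae	photosynthetic
class	Phaeothamniophyceae	photosynthetic
class	Chlorarachniophyceae	photosynthetic
class	Rappemonadea	photosynthetic
division	Chlorophyta	photosynthetic
division	Rhodophyta	photosynthetic
division	Cryptophyta	photosynthetic
division	Haptophyta	photosynthetic
division	Ciliophora	heterotrophic
division	Cercozoa	heterotrophic
division	Radiolaria	heterotrophic
division	Metazoa	heterotrophic
division	Fungi	heterotrophic
division	Apicomplexa	heterotrophic
division	Katablepharidophyta	heterotrophic
division	Opalozoa	heterotrophic
division	Sagenista	heterotrophic
division	Choanoflagellida	heterotrophic
class	Labyrinthulea	heterotrophic
class	MAST-3	heterotrophic
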