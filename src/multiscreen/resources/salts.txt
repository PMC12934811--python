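# Salt / solvate suffixes stripped during drug-name normalization (one per line).
# Edit freely; matching is on whole trailing words after lowercasing.
hydrochloride
hcl
dihydrochloride
hydrobromide
hbr
sulfate
sulphate
hemisulfate
mesylate
dimesylate
besylate
tosylate
maleate
fumarate
hemifumarate
citrate
tartrate
malate
oxalate
succinate
acetate
trifluoroacetate
tfa
phosphate
diphosphate
lactate
sodium
disodium
potassium
calcium
hydrate
monohydrate
dihydrate
trihydrate
hemihydrate
ethanolate
isethionate
pamoate
napsylate
benzoate
carbonate
bitartrate
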