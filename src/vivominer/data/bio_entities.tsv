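# Lexicon of protein and cell-line names used by the bundled fallback tagger
# to emit PROT/CELL token flags (the role the external biomedical tagger's NER
# output plays when that backend is available). Lower-cased surface forms;
# multi-word entries are matched as token n-grams.
# columns: surface <TAB> tag
concanavalin a	PROT
angiotensin	PROT
angiotensin 2	PROT
angiotensin ii	PROT
insulin	PROT
leptin	PROT
interleukin 2	PROT
il-2	PROT
il4	PROT
tnf	PROT
collagen	PROT
apolipoprotein a-i	PROT
apoa1	PROT
dopa	PROT
p388	CELL
l1210	CELL
b16	CELL
hela	CELL
mcf-7	CELL
m5076	CELL
ht-29	CELL
a549	CELL
ehrlich	CELL
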