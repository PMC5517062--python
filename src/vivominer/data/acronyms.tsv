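# 20-entry table of administration-route and dosing-regimen acronyms expanded
# during description normalization. Reconstructed from standard pharmacology
# usage; entries marked verified appear verbatim in curator descriptions.
# columns: acronym <TAB> expansion <TAB> kind
sc	subcutaneous	route
iv	intravenous	route
ip	intraperitoneal	route
im	intramuscular	route
po	peroral	route
ig	intragastric	route
icv	intracerebroventricular	route
id	intradermal	route
ic	intracisternal	route
inh	inhalation	route
qd	daily	regimen
od	once daily	regimen
bid	twice daily	regimen
tid	three times daily	regimen
qid	four times daily	regimen
qod	every other day	regimen
qw	weekly	regimen
biw	twice weekly	regimen
tiw	three times weekly	regimen
prn	as needed	regimen
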