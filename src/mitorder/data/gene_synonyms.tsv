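# Synonym table for canonical mitochondrial gene names.
# One mapping per line: <synonym> TAB <canonical token>.
# Synonyms are matched after normalization: lowercase, with whitespace,
# hyphens, underscores and dots removed ("tRNA-Ala" -> "trnaala").
# Bare "tRNA-Leu"/"tRNA-Ser" spellings are disambiguated in code from the
# codon family or anticodon and are deliberately absent here.
cox1	cox1
coi	cox1
co1	cox1
coxi	cox1
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunit1	cox1
cytochromeoxidasesubunit1	cox1
cytochromeoxidasesubuniti	cox1
cox2	cox2
coii	cox2
co2	cox2
coxii	cox2
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunit2	cox2
cytochromeoxidasesubunit2	cox2
cox3	cox3
coiii	cox3
co3	cox3
coxiii	cox3
cytochromecoxidasesubunitiii	cox3
cytochromecoxidasesubunit3	cox3
cytochromeoxidasesubunit3	cox3
cob	cob
cytb	cob
cb	cob
cytochromeb	cob
atp6	atp6
atpase6	atp6
atpasesubunit6	atp6
atpsynthasef0subunit6	atp6
atpsynthasesubunit6	atp6
atp8	atp8
atpase8	atp8
atpasesubunit8	atp8
atpsynthasef0subunit8	atp8
atpsynthasesubunit8	atp8
nad1	nad1
nd1	nad1
nadhdehydrogenasesubunit1	nad1
nad2	nad2
nd2	nad2
nadhdehydrogenasesubunit2	nad2
nad3	nad3
nd3	nad3
nadhdehydrogenasesubunit3	nad3
nad4	nad4
nd4	nad4
nadhdehydrogenasesubunit4	nad4
nad4l	nad4L
nd4l	nad4L
nadhdehydrogenasesubunit4l	nad4L
nad5	nad5
nd5	nad5
nadhdehydrogenasesubunit5	nad5
nad6	nad6
nd6	nad6
nadhdehydrogenasesubunit6	nad6
rrnl	rrnL
lrrna	rrnL
16s	rrnL
16srrna	rrnL
16sribosomalrna	rrnL
rrn16	rrnL
largesubunitribosomalrna	rrnL
lsurrna	rrnL
rrns	rrnS
srrna	rrnS
12s	rrnS
12srrna	rrnS
12sribosomalrna	rrnS
rrn12	rrnS
smallsubunitribosomalrna	rrnS
ssurrna	rrnS
cr	CR
controlregion	CR
putativecontrolregion	CR
dloop	CR
atrichregion	CR
trna	trnA
trnaala	trnA
a	trnA
trnr	trnR
trnaarg	trnR
r	trnR
trnn	trnN
trnaasn	trnN
n	trnN
trnd	trnD
trnaasp	trnD
d	trnD
trnc	trnC
trnacys	trnC
c	trnC
trnq	trnQ
trnagln	trnQ
q	trnQ
trne	trnE
trnaglu	trnE
e	trnE
trng	trnG
trnagly	trnG
g	trnG
trnh	trnH
trnahis	trnH
h	trnH
trni	trnI
trnaile	trnI
i	trnI
trnk	trnK
trnalys	trnK
k	trnK
trnm	trnM
trnamet	trnM
m	trnM
trnf	trnF
trnaphe	trnF
f	trnF
trnp	trnP
trnapro	trnP
p	trnP
trnt	trnT
trnathr	trnT
t	trnT
trnw	trnW
trnatrp	trnW
w	trnW
trny	trnY
trnatyr	trnY
y	trnY
trnv	trnV
trnaval	trnV
v	trnV
trnl1	trnL1
l1	trnL1
trnl2	trnL2
l2	trnL2
trns1	trnS1
s1	trnS1
trns2	trnS2
s2	trnS2
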