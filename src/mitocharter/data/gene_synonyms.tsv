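# alias	canonical token
# Protein-coding genes
cox1	cox1
coi	cox1
co1	cox1
coxi	cox1
cox 1	cox1
mt-co1	cox1
cytochrome c oxidase subunit 1	cox1
cytochrome c oxidase subunit i	cox1
cytochrome oxidase subunit 1	cox1
cytochrome oxidase subunit i	cox1
cox2	cox2
coii	cox2
co2	cox2
coxii	cox2
cox 2	cox2
mt-co2	cox2
cytochrome c oxidase subunit 2	cox2
cytochrome c oxidase subunit ii	cox2
cox3	cox3
coiii	cox3
co3	cox3
coxiii	cox3
cox 3	cox3
mt-co3	cox3
cytochrome c oxidase subunit 3	cox3
cytochrome c oxidase subunit iii	cox3
cob	cob
cytb	cob
cyt b	cob
cyb	cob
mt-cyb	cob
cytochrome b	cob
cytochrome b apoenzyme	cob
nad1	nad1
nd1	nad1
nadh1	nad1
nadh dehydrogenase subunit 1	nad1
nad2	nad2
nd2	nad2
nadh2	nad2
nadh dehydrogenase subunit 2	nad2
nad3	nad3
nd3	nad3
nadh3	nad3
nadh dehydrogenase subunit 3	nad3
nad4	nad4
nd4	nad4
nadh4	nad4
nadh dehydrogenase subunit 4	nad4
nad4l	nad4l
nd4l	nad4l
nadh4l	nad4l
nadh dehydrogenase subunit 4l	nad4l
nad5	nad5
nd5	nad5
nadh5	nad5
nadh dehydrogenase subunit 5	nad5
nad6	nad6
nd6	nad6
nadh6	nad6
nadh dehydrogenase subunit 6	nad6
atp6	atp6
atpase6	atp6
atpase 6	atp6
atp synthase f0 subunit 6	atp6
atp synthase subunit 6	atp6
atp8	atp8
atpase8	atp8
atpase 8	atp8
atp synthase f0 subunit 8	atp8
atp synthase subunit 8	atp8
# Ribosomal RNAs
rrnl	rrnL
rrn l	rrnL
16s	rrnL
16s rna	rrnL
16s rrna	rrnL
16s ribosomal rna	rrnL
l-rrna	rrnL
lrrna	rrnL
l rrna	rrnL
rrn16	rrnL
large subunit ribosomal rna	rrnL
rrns	rrnS
rrn s	rrnS
12s	rrnS
12s rna	rrnS
12s rrna	rrnS
12s ribosomal rna	rrnS
s-rrna	rrnS
srrna	rrnS
s rrna	rrnS
rrn12	rrnS
small subunit ribosomal rna	rrnS
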