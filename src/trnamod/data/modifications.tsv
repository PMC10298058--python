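# Modified-nucleoside registry: free-nucleoside formulas, cleavage/labeling flags,
# and informational position annotations for the coconut tRNA pool.
short_name	parent_base	formula	pyrimidine_like	guanosine_like	ce_reactive	blocks_rnase_a	blocks_rnase_t1	esi_positive	canonical	known_positions
A	A	C10H13N5O4	0	0	0	0	0	1	1	-
C	C	C9H13N3O5	1	0	0	0	0	1	1	-
G	G	C10H13N5O5	0	1	0	0	0	1	1	-
U	U	C9H12N2O6	1	0	0	0	0	1	1	-
I	A	C10H12N4O5	0	1	1	0	0	1	0	5,6,7,14,24,28,34,37,46,47,48,59,65,67
Im	A	C11H14N4O5	0	1	0	0	1	1	0	64
m^6^A	A	C11H15N5O4	0	0	0	0	0	1	0	37
Am	A	C11H15N5O4	0	0	0	0	0	1	0	4
m^1^A	A	C11H15N5O4	0	0	0	0	0	1	0	9,14,15,22,58
i^6^A	A	C15H21N5O4	0	0	0	0	0	1	0	37
io^6^A	A	C15H21N5O5	0	0	0	0	0	1	0	37
ms^2^io^6^A	A	C16H23N5O5S	0	0	0	0	0	1	0	37
t^6^A	A	C15H20N6O8	0	0	0	0	0	1	0	37
ct^6^A	A	C15H18N6O7	0	0	0	0	0	1	0	37
ms^2^t^6^A	A	C16H22N6O8S	0	0	0	0	0	1	0	37
ms^2^i^6^A	A	C16H23N5O4S	0	0	0	0	0	1	0	37
Ar(p)	A	C15H22N5O11P	0	0	0	0	0	0	0	64
Ψ	U	C9H12N2O6	1	0	1	0	0	1	0	1,3,4,8,11,12,25,27,28,29,31,32,33,35,39,40,41,47,48,49,50,55,59,60,67,71,73
D	U	C9H14N2O6	1	0	0	0	0	1	0	16,17,19,20,20a
Um	U	C10H14N2O6	1	0	0	1	0	1	0	4,32,34,38,39,44
m^5^U	U	C10H14N2O6	1	0	0	0	0	1	0	54
ncm^5^U	U	C11H15N3O7	1	0	0	0	0	1	0	34
cmnm^5^Um	U	C13H19N3O8	1	0	0	1	0	1	0	34
ho^5^U	U	C9H12N2O7	1	0	0	0	0	1	0	34
s^2^U	U	C9H12N2O5S	1	0	0	0	0	1	0	32
s^4^U	U	C9H12N2O5S	1	0	0	0	0	1	0	8
Cm	C	C10H15N3O5	1	0	0	1	0	1	0	4,13,32,34,60
m^5^C	C	C10H15N3O5	1	0	0	0	0	1	0	11,38,40,48,49,50,72
m^3^C	C	C10H15N3O5	1	0	0	0	0	1	0	32
ac^4^C	C	C11H15N3O6	1	0	0	0	0	1	0	34
m^1^G	G	C11H15N5O5	0	1	0	0	1	1	0	9,37,39,40
m^7^G	G	C11H15N5O5	0	1	0	0	1	1	0	34,45,46,47,49
m^2^G	G	C11H15N5O5	0	1	0	0	1	1	0	4,5,10
Gm	G	C11H15N5O5	0	1	0	0	1	1	0	-
m^2,2^G	G	C12H17N5O5	0	1	0	0	1	1	0	26,27
imG-14	G	C13H15N5O5	0	1	0	0	1	1	0	37
yW	G	C21H28N6O9	0	1	0	0	1	1	0	37
yW-86	G	C17H22N6O7	0	1	0	0	1	1	0	37
yW-72	G	C18H24N6O7	0	1	0	0	1	1	0	37
yW-58	G	C19H26N6O7	0	1	0	0	1	1	0	37
OHyW	G	C21H28N6O10	0	1	0	0	1	1	0	37
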