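# Physicochemical properties of the 20 standard amino acids.
# vdw_volume: side-chain-inclusive Van der Waals volumes (Å³), Zamyatnin 1972
#   (Prog. Biophys. Mol. Biol. 24, 107) as tabulated in Creighton, Proteins.
# apparent_volume: mean residue volumes in folded proteins (Å³),
#   Harpaz, Gerstein & Chothia 1994, Structure 2, 641.
# asa: water-accessible surface area of X in Gly-X-Gly (Å²),
#   Miller, Janin, Lesk & Chothia 1987, J. Mol. Biol. 196, 641.
# hclass: hydropathy class used for class contrasts; His is treated as POLAR
#   by default (configurable at load time).
code	name	vdw_volume	apparent_volume	asa	hclass
A	Alanine	88.6	90.1	113.0	HYDROPHOBIC
R	Arginine	173.4	192.8	241.0	POSITIVE
N	Asparagine	114.1	127.5	158.0	POLAR
D	Aspartate	111.1	117.1	151.0	NEGATIVE
C	Cysteine	108.5	103.5	140.0	HYDROPHOBIC
Q	Glutamine	143.9	149.4	189.0	POLAR
E	Glutamate	138.4	140.8	183.0	NEGATIVE
G	Glycine	60.1	63.8	85.0	POLAR
H	Histidine	153.2	159.3	194.0	POLAR
I	Isoleucine	166.7	164.9	182.0	HYDROPHOBIC
L	Leucine	166.7	164.6	180.0	HYDROPHOBIC
K	Lysine	168.6	170.0	211.0	POSITIVE
M	Methionine	162.9	167.7	204.0	HYDROPHOBIC
F	Phenylalanine	189.9	193.5	218.0	HYDROPHOBIC
P	Proline	112.7	123.1	143.0	POLAR
S	Serine	89.0	94.2	122.0	POLAR
T	Threonine	116.1	120.0	146.0	POLAR
W	Tryptophan	227.8	231.7	259.0	HYDROPHOBIC
Y	Tyrosine	193.6	197.1	229.0	POLAR
V	Valine	140.0	139.1	160.0	HYDROPHOBIC
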