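{
 "version": "biosynkey-default-1.0",
 "keys": [
  {
   "name": "indole_c2n",
   "group": "indole unit",
   "pathway": "shikimate",
   "smarts_raw": "c1ccc2c(c1)c(c[nH]2)CCN",
   "is_dewick_block": true
  },
  {
   "name": "phenethylamine_c6c2n",
   "group": "phenylpropanoids",
   "pathway": "shikimate",
   "smarts_raw": "c1ccccc1CCN",
   "is_dewick_block": true
  },
  {
   "name": "phenylpropanoid_c6c3",
   "group": "phenylpropanoids",
   "pathway": "shikimate",
   "smarts_raw": "c1ccccc1CCC",
   "is_dewick_block": true
  },
  {
   "name": "benzyl_c6c1",
   "group": "phenylpropanoids",
   "pathway": "shikimate",
   "smarts_raw": "c1ccccc1C",
   "is_dewick_block": true
  },
  {
   "name": "malonyl_c3",
   "group": "acetate units",
   "pathway": "acetate",
   "smarts_raw": "O=CCC=O",
   "is_dewick_block": false
  },
  {
   "name": "acetyl_c2",
   "group": "acetate units",
   "pathway": "acetate",
   "smarts_raw": "CC=O",
   "is_dewick_block": true
  },
  {
   "name": "isoprene_c5",
   "group": "isoprene",
   "pathway": "terpenoid",
   "smarts_raw": "CC(C)CC",
   "is_dewick_block": true
  },
  {
   "name": "pyranose",
   "group": "sugars",
   "pathway": "carbohydrate",
   "smarts_raw": "C1OC(O)C(O)C(O)C1O",
   "is_dewick_block": false
  },
  {
   "name": "furanose",
   "group": "sugars",
   "pathway": "carbohydrate",
   "smarts_raw": "C1OC(O)C(O)C1O",
   "is_dewick_block": false
  },
  {
   "name": "pyruvate_c3",
   "group": "pyruvate",
   "pathway": "carbohydrate",
   "smarts_raw": "CC(=O)C(=O)O",
   "is_dewick_block": true
  },
  {
   "name": "glycosidic_oxygen",
   "group": "sugars",
   "pathway": "carbohydrate",
   "smarts_raw": "OCO",
   "is_dewick_block": false
  },
  {
   "name": "arginine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "NC(=N)NCCCC(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "histidine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "C(c1cnc[nH]1)C(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "lysine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "NCCCCC(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "isoleucine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "CCC(C)C(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "leucine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "CC(C)CC(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "proline",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "OC(=O)C1CCCN1",
   "is_dewick_block": false
  },
  {
   "name": "threonine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "CC(O)C(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "valine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "CC(C)C(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "cysteine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "SCC(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "serine",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "OCC(N)C(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "alpha_amino_acid",
   "group": "amino acids",
   "pathway": "amino-acid",
   "smarts_raw": "NCC(=O)O",
   "is_dewick_block": false
  },
  {
   "name": "methyl_c1",
   "group": "methyl",
   "pathway": "amino-acid",
   "smarts_raw": "[#6H3]",
   "is_dewick_block": true
  },
  {
   "name": "ring6_carbocycle",
   "group": "carbon rings",
   "pathway": "none",
   "smarts_raw": "C1CCCCC1",
   "is_dewick_block": false
  },
  {
   "name": "phosphate",
   "group": "phosphate",
   "pathway": "none",
   "smarts_raw": "OP(=O)(O)O",
   "is_dewick_block": false
  },
  {
   "name": "ring5_carbocycle",
   "group": "carbon rings",
   "pathway": "none",
   "smarts_raw": "C1CCCC1",
   "is_dewick_block": false
  },
  {
   "name": "ring4_carbocycle",
   "group": "carbon rings",
   "pathway": "none",
   "smarts_raw": "C1CCC1",
   "is_dewick_block": false
  },
  {
   "name": "carboxyl",
   "group": "oxygen decorations",
   "pathway": "none",
   "smarts_raw": "[#6](~[#8D1H0])~[#8H1]",
   "is_dewick_block": false
  },
  {
   "name": "ring3_carbocycle",
   "group": "carbon rings",
   "pathway": "none",
   "smarts_raw": "C1CC1",
   "is_dewick_block": false
  },
  {
   "name": "carbonyl",
   "group": "oxygen decorations",
   "pathway": "none",
   "smarts_raw": "[#8D1H0]~[#6]",
   "is_dewick_block": false
  },
  {
   "name": "primary_amine",
   "group": "nitrogen decorations",
   "pathway": "none",
   "smarts_raw": "[#7H2]~[#6]",
   "is_dewick_block": false
  },
  {
   "name": "bromine",
   "group": "halogens",
   "pathway": "none",
   "smarts_raw": "Br",
   "is_dewick_block": false
  },
  {
   "name": "chlorine",
   "group": "halogens",
   "pathway": "none",
   "smarts_raw": "Cl",
   "is_dewick_block": false
  },
  {
   "name": "fluorine",
   "group": "halogens",
   "pathway": "none",
   "smarts_raw": "F",
   "is_dewick_block": false
  },
  {
   "name": "hydroxyl",
   "group": "oxygen decorations",
   "pathway": "none",
   "smarts_raw": "[#8H1]",
   "is_dewick_block": false
  },
  {
   "name": "iodine",
   "group": "halogens",
   "pathway": "none",
   "smarts_raw": "I",
   "is_dewick_block": false
  },
  {
   "name": "sulfur",
   "group": "sulfur decorations",
   "pathway": "none",
   "smarts_raw": "[#16]",
   "is_dewick_block": false
  },
  {
   "name": "coa_thioester",
   "group": "coenzymes",
   "pathway": "none",
   "smarts_raw": "C(=O)SCCNC(=O)CCNC(=O)",
   "is_dewick_block": false
  },
  {
   "name": "nucleotide_purine",
   "group": "coenzymes",
   "pathway": "none",
   "smarts_raw": "c1ncc2[nH]cnc2n1",
   "is_dewick_block": false
  }
 ]
}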