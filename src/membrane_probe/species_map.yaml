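# Editable residue/atom-name -> species mapping used by the trajectory readers
# and the per-species electron counts used by electron-density profiles.
#
# Atom names are matched by longest prefix within a residue (so "T3" and "T10"
# both resolve through the "T" entry).  Electron counts are integer electrons
# per coarse bead: the lipid head bead lumps the phosphocholine/glycerol
# backbone (~164 e for a PC head), each tail bead lumps roughly two CH2/CH
# units of the oleoyl chains, and the flavonoid bead carries the electron count
# of a whole polyphenol (quercetin-sized).
residues:
  DOPC:
    HD: LIPID_HEAD
    T: LIPID_TAIL
  DDA:
    C: DDA_C
    O: DDA_O
    H: DDA_H
  SOL:
    OW: WATER_O
    HW: WATER_H
  FLV:
    F: FLAV
electrons:
  LIPID_HEAD: 164
  LIPID_TAIL: 27
  DDA_C: 8
  DDA_O: 8
  DDA_H: 1
  WATER_O: 8
  WATER_H: 1
  FLAV: 150
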