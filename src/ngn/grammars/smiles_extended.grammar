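# Practical SMILES: organic-subset and aromatic element tokens, bond symbols,
# single-digit ring closures, branches (optionally bond-led) and bracket atoms
# [isotope? element chiral? Hcount? charge?].  Hydrogen-suppressed; valence is
# not checked (syntax only).
smiles <- chain
chain <- unit
chain <- unit chain
chain <- unit bond chain
unit <- atom
unit <- atom decs
atom <- elem
atom <- bracket
decs <- dec
decs <- dec decs
dec <- ring
dec <- branch
ring <- digit
branch <- '(' chain_rparen
branch <- '(' bond chain_rparen
chain_rparen <- chain rparen
rparen <- ')'
bracket <- '[' bcore rbrack
bcore <- belem
bcore <- isotope belem
bcore <- belem bmods
bcore <- isotope belem bmods
isotope <- digit
isotope <- digit isotope
belem <- elem
belem <- hydrogen
hydrogen <- 'H'
bmods <- bmod
bmods <- bmod bmods
bmod <- chiral
bmod <- hcount
bmod <- charge
chiral <- '@' '@@'
hcount <- hydrogen
hcount <- hydrogen digit
charge <- sign
charge <- sign digit
sign <- '+' '-'
rbrack <- ']'
bond <- '-' '=' '#' '/' '\'
elem <- 'B' 'C' 'N' 'O' 'P' 'S' 'F' 'Cl' 'Br' 'I' 'b' 'c' 'n' 'o' 'p' 's'
digit <- '0' '1' '2' '3' '4' '5' '6' '7' '8' '9'
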