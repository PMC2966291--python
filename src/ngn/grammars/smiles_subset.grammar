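# 10-rule SMILES fragment: branched chains of aliphatic C and O.
smiles <- chain
chain <- atom
chain <- atom chain
chain <- atom Nbranch chain
atom <- 'C'
atom <- 'O'
Nbranch <- branch
branch <- '(' chain_rparen
chain_rparen <- chain rparen
rparen <- ')'
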