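# Simplified InChI: version header, formula layer, and the /c (connectivity)
# and /h (hydrogen) layers treated as opaque token sequences.  Not the full
# InChI specification.
inchi <- header formula
inchi <- header formula cpart
inchi <- header formula hlayer
header <- prefix version
prefix <- 'InChI='
version <- '1S' '1'
formula <- fslash ftoks
fslash <- '/'
ftoks <- ftok
ftoks <- ftok ftoks
ftok <- elem
ftok <- digit
cpart <- clayer
cpart <- clayer hlayer
clayer <- cslash ctoks
cslash <- '/c'
ctoks <- ctok
ctoks <- ctok ctoks
ctok <- digit
ctok <- dash
ctok <- lpar
ctok <- rpar
ctok <- comma
hlayer <- hslash htoks
hslash <- '/h'
htoks <- htok
htoks <- htok htoks
htok <- digit
htok <- dash
htok <- comma
htok <- lpar
htok <- rpar
htok <- hsym
hsym <- 'H'
dash <- '-'
lpar <- '('
rpar <- ')'
comma <- ','
elem <- 'C' 'H' 'N' 'O' 'P' 'S' 'B' 'F' 'I' 'Cl' 'Br'
digit <- '0' '1' '2' '3' '4' '5' '6' '7' '8' '9'
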