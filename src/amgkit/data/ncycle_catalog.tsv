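symbol	ko	keyword_regex
focA	K03459	\bfocA\b|formate[ /_-]?nitrite transporter|nitrite transporter
nirA	K00366	\bnirA\b|ferredoxin[ -]?nitrite reductase
nirK	K00368	\bnirK\b|copper[ -]?containing nitrite reductase|nitrite reductase \(NO[ -]?forming\)
norB	K04561	\bnorB\b|nitric[ -]?oxide reductase
amoC	K10946	\bamoC\b|ammonia monooxygenase subunit C|ammonia monooxygenase
glnK	K04752	\bglnK\b|nitrogen regulatory protein P-?II\b|\bPII\b signal transduction
amtB	K03320	\bamtB\b|ammonium transporter|ammonia channel
ompL	K07272	\bompL\b|outer membrane porin L
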