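>R112C_E3 offset=101
QARLGADMEDVCGRLV
>R112C_E4 offset=101
QARLGADMEDVRGRLV
>RP1 offset=4 ss=6,13,18,25,31,42
DRCERNEFQCQDGKCISYKWVCDGSAECQDGSDESQETC
>RP2 offset=45 ss=47,54,61,68,74,83
VTCKSGDFSCGGRVNRCIPQFWRCDGQVDCDNGSDEQGCP
>RP3 offset=86 ss=88,95,100,107,113,122
KTCSQDEFRCHDGKCISRQFVCDSDRDCLDGSDEASCP
>RP4 offset=127 ss=127,134,139,146,152,163
CGPASFQCNSSTCIPQLWACDNDPDCEDGSDEWPQRCR
>RP5 offset=174 ss=176,183,188,195,201,210
SPCSAFEFHCLSGECIHSSWRCDGGPDCKDKSDEENCA
>RP6 offset=213 ss=215,222,227,234,240,249
ATCRPDEFQCSDGNCIHGSRQCDREYDCKDMSDEVGCV
>RP7 offset=253 ss=255,263,268,275,281,292
TLCEGPNKFKCHSGECITLDKVCNMARDCRDWSDEPIKEC
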