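>focA synthetic stand-in protein for the focA nitrite transporter fixture
MKALTEGFNVSLIGAWLVTGAAFSMGGYELVTHNPLAVIGKSVFGNLIGSALFPLMIAGG
TLAGAENLVRTAPMSVFAKDILGNWVGCLAVMLFAGVSHE
>nirA synthetic stand-in protein for the nirA ferredoxin-nitrite reductase fixture
MSDKLTQRVEAHPNLRFTSGQFMVGVTGDLQAYSERLAKELGPEWCDITTRQNLQLRWIK
LEDVPEILNRLEAVGLSSRQSGGNTVRNVTACPYAGLADE
>nirK synthetic stand-in protein for the nirK copper nitrite reductase fixture
MAHPEVKTLNAGDSVEVWGFNGQIPGPLIRVRQGDTVELHLKNDLPEATTIHWHGLPVPN
AMDGVPGLSFPGIKPGETFTYKFPLRQSGTYWYHSHTMGQ
>norB synthetic stand-in protein for the norB nitric oxide reductase fixture
MGNWFKTLAVSHLPLALFGGALALTVGWTWLFQTGMHVPA
DLTEFYQVMTAHGVLMVFWFLIPFSIGFGNYIVPLMIGAR
>amoC synthetic stand-in protein for the amoC ammonia monooxygenase fixture
MSTDKLASFHAEFSKAIDWGWVAFFAVLVGINYVQPGAFM
TGHLDTWQMIFTPVWLPFNMLLEGVAYRMVDTHGFHWEDA
>glnK synthetic stand-in protein for the glnK PII nitrogen regulator fixture
MKLVTAIIKPFKLDDVREALSSIGVQGLTVTEVKGFGRQK
GHTELYRGAEYSVNFLPKVKIDVAIPDDIVDTCVDTIIRT
>amtB synthetic stand-in protein for the amtB ammonium transporter fixture
MNPSLMALNTGDTAWMLTSTALVLLMTIPGLALFYGGLVR
SKNVLSVLMQVFAIFSLISVLWVVYGYSLAFGEGNSFFGW
>ompL synthetic stand-in protein for the ompL outer-membrane porin fixture
MKKLALTAAVSLAFGANAQLYGRAFLSLDYVNAEGTKQDG
SLGFDSNFELENGWSAGAALELGLDKDWSLDAGYQYLGKA
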