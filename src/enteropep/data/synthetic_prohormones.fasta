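>SYNP001|SST synthetic prohormone stand-in
MKLSALLLVLCLTGAVFSAQAPSDGELNQWMEHSTDLQKRSANSEPAMAPLERSRKAGCENFFWETFTSC
>SYNP002|NPW synthetic prohormone stand-in
MGLRSVLPLLLLSMVSGAWSWYEHTAGHLANSGKRTDLESAVSEPLAYM
>SYNP003|PPY synthetic prohormone stand-in
MAAARLCLSLLLLSTCVALLAPLEPVYPGDNATPEQMAQYAADLREYINMLTEPEYGKRLNEYLTWPESQSPNAVEELTQ
>SYNP004|MLN synthetic prohormone stand-in
MVSSELSVCLMLCLLTAGSAFVPIFTYGELQEMQEEDNVELTKKSMDENVDFAHSELQ
>SYNP005|SCG2 synthetic prohormone stand-in
MLSETLPLLSLFLLSLSTEATNEIVEEQYTPQSLKRLPDSAHFQNTESMELDRRFPVESTHLAGELSNGKRSGQLDESAVTEWQS
>SYNP006|CHGA synthetic prohormone stand-in
MRSAAVLALLLCAGQVFSAELPVNSPMNEGDTESMALSKKSSMELTSEAFENGHSQELAKRELQDLAHQGEIAESGRREDSLEALSEVLAHM
>SYNP007|VGF synthetic prohormone stand-in
MKALTLSATLFCLLLTNGLAAPPGEAHYQEHDLENSALMSRKTLQPNSALEESVGSKRNEQSWESAHFDSTASGKKEHQEALASHM
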