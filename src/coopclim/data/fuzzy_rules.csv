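ec\e,NB,NM,NS,ZO,PS,PM,PB
NB,PB/NB/PS/PB,PB/NB/NS/PM,PM/NM/NB/PS,PS/NM/NB/ZO,PS/NS/NB/NS,ZO/PS/NM/NM,ZO/PS/PS/NB
NM,PB/NB/PS/PM,PB/NB/NS/PS,PM/NM/NB/ZO,PS/NS/NM/NS,PS/NS/NM/NM,ZO/PS/NS/NB,NS/PS/PM/NB
NS,PM/NB/PS/PS,PM/NM/NS/ZO,PM/NS/NM/NS,PS/NS/NM/NM,ZO/PS/NS/NB,NS/PM/NS/NB,NS/PM/PM/NB
ZO,PM/NM/PS/PS,PM/NM/NS/ZO,PS/NS/NS/NS,ZO/PS/NS/NB,NS/PM/NS/NB,NM/PB/NS/NB,NM/PB/PM/NB
PS,PS/NM/PS/PS,PS/NS/PS/ZO,ZO/PS/PS/NS,NS/PM/PS/NM,NS/PM/PS/NB,NM/PB/PS/NB,NM/PB/PS/NB
PM,PS/PS/PB/PM,ZO/PS/NS/PS,NS/PM/PM/ZO,NM/PM/PM/NS,NM/PB/PM/NM,NM/PB/PM/NB,NB/PB/PB/NB
PB,ZO/PS/PB/PB,ZO/PS/PB/PM,NM/PM/PB/PS,NM/PB/PB/ZO,NM/PB/PM/NS,NB/PB/PM/NM,NB/PB/PB/NB
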