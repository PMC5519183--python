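>SYNREF-I-N|I-N
WRKYGQKIEIAFPFNNQCAAAACAAAAAAAAAAAAAAAAAAAAAAHAHGLFDKM
>SYNREF-I-C|I-C
WRKYGQKDYEMKIEYIKCAAAACAAAAAAAAAAAAAAAAAAAAAAHAHMSTQDF
>SYNREF-IIa|IIa
WRKYGQKLVNRSPKAQSCAAAACAAAAAAAAAAAAAAAAAAAAAAHAHFSMALT
>SYNREF-IIb|IIb
WRKYGQKQAILSSQVRSCAAAACAAAAAAAAAAAAAAAAAAAAAAHAHYAGGGF
>SYNREF-IIc|IIc
WRKYGQKLNEEFIRSQICAAAACAAAAAAAAAAAAAAAAAAAAAAHAHQNGYFL
>SYNREF-IId|IId
WRKYGQKGAPYLRVRRNCAAAACAAAAAAAAAAAAAAAAAAAAAAHAHKVQNTY
>SYNREF-IIe|IIe
WRKYGQKYFEEGGDMDSCAAAACAAAAAAAAAAAAAAAAAAAAAAHAHDMVNAI
>SYNREF-III|III
WRKYGQKASILSKNNTGCAAAAAAACAAAAAAAAAAAAAAAAAAAAAAAAHACRRMYQQ
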