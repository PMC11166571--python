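species,fad,lad,group
Australopithecus afarensis,3.70,3.00,non-Homo
Australopithecus africanus,3.00,2.40,non-Homo
Australopithecus anamensis,4.20,3.90,non-Homo
Australopithecus bahrelghazali,3.58,3.58,non-Homo
Australopithecus deyiremeda,3.50,3.30,non-Homo
Australopithecus garhi,2.50,2.45,non-Homo
Australopithecus sediba,1.98,1.98,non-Homo
Homo erectus,1.81,0.03,Homo
Homo floresiensis,0.06,0.02,Homo
Homo habilis,2.35,1.65,Homo
Homo heidelbergensis,0.70,0.10,Homo
Homo neanderthalensis,0.13,0.04,Homo
Homo sapiens,0.20,0.00,Homo
Paranthropus aethiopicus,2.66,2.30,non-Homo
Paranthropus boisei,2.30,1.30,non-Homo
Paranthropus robustus,2.00,1.00,non-Homo
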