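year,new_cases,pop_under19,pop_19
1997,156,491915,29946
1998,166,479240,30505
1999,177,467980,30061
2000,214,456145,29730
2001,254,444360,28820
2002,230,433884,27472
2003,329,424472,26949
2004,354,415850,26661
2005,316,408383,25069
2006,303,403028,25880
2007,224,397958,26388
2008,334,394304,24955
2009,229,392987,23184
2010,299,393176,22898
2011,329,393202,21506
2012,378,394681,20669
2013,,396657,20366
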