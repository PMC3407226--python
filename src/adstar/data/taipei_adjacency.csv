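# District adjacency for the 12 Taipei City districts, hand-built from the
# city map (two districts are neighbours when they share part of a boundary).
# Undirected edge list, one edge per line.
Beitou,Shihlin
Shihlin,Datong
Shihlin,Jhongshan
Shihlin,Neihu
Neihu,Jhongshan
Neihu,Songshan
Neihu,Nangang
Datong,Jhongshan
Datong,Wanhua
Datong,Jhongjheng
Jhongshan,Songshan
Jhongshan,Daan
Jhongshan,Jhongjheng
Songshan,Sinyi
Songshan,Daan
Songshan,Nangang
Nangang,Sinyi
Nangang,Wunshan
Sinyi,Daan
Sinyi,Wunshan
Daan,Jhongjheng
Daan,Wunshan
Wanhua,Jhongjheng
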