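# Synthetic per-district child population counts playing the role of the 2000
# Census denominators. Values are plausible round numbers for Taipei City
# districts (preschool = ages 0-6, school = ages 7-14, all = their sum); they
# are a constructed stand-in, not census data.
district,age_group,population
Songshan,preschool,16500
Songshan,school,20600
Songshan,all,37100
Daan,preschool,25200
Daan,school,31500
Daan,all,56700
Datong,preschool,10300
Datong,school,12900
Datong,all,23200
Jhongshan,preschool,17400
Jhongshan,school,21700
Jhongshan,all,39100
Neihu,preschool,19500
Neihu,school,24400
Neihu,all,43900
Nangang,preschool,8900
Nangang,school,11100
Nangang,all,20000
Shihlin,preschool,23000
Shihlin,school,28800
Shihlin,all,51800
Beitou,preschool,20100
Beitou,school,25100
Beitou,all,45200
Sinyi,preschool,18800
Sinyi,school,23500
Sinyi,all,42300
Jhongjheng,preschool,13000
Jhongjheng,school,16300
Jhongjheng,all,29300
Wanhua,preschool,15400
Wanhua,school,19300
Wanhua,all,34700
Wunshan,preschool,21000
Wunshan,school,26300
Wunshan,all,47300
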