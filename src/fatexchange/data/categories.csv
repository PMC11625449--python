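id,name
1,whole milk
2,"low-fat, skimmed and fortified milks"
3,cheeses
4,yogurts
5,butter
6,spreading fats and oils
7,fresh meat
8,processed meats
9,poultry
10,"fish, fish products and fish dishes"
11,eggs and egg dishes
12,bread and rolls
13,ready-to-eat breakfast cereals
14,biscuits
15,cakes and pastries
16,chocolate confectionery
17,sugar confectionery
18,savoury snacks
19,desserts and puddings
20,"potatoes boiled, baked and mashed"
21,"potatoes chipped, fried and roasted"
22,rice and pasta
23,fruit
24,vegetables
25,non-alcoholic beverages
26,other foods
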