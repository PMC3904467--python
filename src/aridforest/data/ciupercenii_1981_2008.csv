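category,Bodies of water,Agricultural,Built areas,Marshes,Sandy areas,Poplar,False-acacia,Willow,Total 2008
Bodies of water,11.9,1.9,0.1,0.7,-,0.3,-,-,14.9
Agricultural,166.9,20995.7,55,1747.5,76.3,1030.4,2275.2,6.8,26353.8
Built areas,57,481.3,1665.3,3.8,-,3.9,13.3,-,2224.6
Marshes,116.7,500.4,-,1448.4,0.2,14.8,8,-,2088.5
Sandy areas,0.9,204,-,5,72.6,17.7,9.5,-,309.7
Poplar,4.1,191.1,-,13.1,0.8,1720,28.4,-,1957.5
False-acacia,0.3,897.1,12.4,13,2.1,95,6566.7,-,7586.6
Willow,-,6.2,-,-,-,0.3,49.7,83.6,139.8
Total 1981,357.8,23277.7,1732.8,3231.5,152,2882.4,8950.8,90.4,40675.4
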