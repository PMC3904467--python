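category,Bodies of water,Agricultural,Built areas,Marshes,Sandy areas,Poplar,False-acacia,Oak,Total 2008
Bodies of water,1.2,0.2,-,-,-,-,-,-,1.4
Agricultural,28,23819.8,87.4,3646.3,61.4,137.7,747.5,42,28570.1
Built areas,-,152.3,1227.2,5.2,-,-,1.1,-,1385.8
Marshes,0.3,122.1,0.5,705.9,-,1.4,0.5,0.5,831.2
Sandy areas,-,112.5,-,5.7,9.3,8.2,-,-,135.7
Poplar,-,52.4,-,5.2,-,336.3,0.4,-,394.3
False-acacia,7.7,469.6,0.9,49.3,-,0.1,2825.5,0.3,3353.4
Oak,5.4,44.5,-,14.4,-,-,0.2,664.6,729.1
Total 1981,42.6,24773.4,1316,4432,70.7,483.7,3575.2,707.4,35401
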