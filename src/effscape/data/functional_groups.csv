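code,name,guild
1,Long-tongued large bees,Hymenoptera
2,Long-tongued medium-sized bees,Hymenoptera
3,Short-tongued large bees,Hymenoptera
4,Short-tongued medium-sized bees,Hymenoptera
5,Short-tongued small bees,Hymenoptera
6,Short-tongued extra small bees,Hymenoptera
7,Honeybees,Hymenoptera
8,Pollen wasps,Hymenoptera
9,Large nectar-feeding wasps,Hymenoptera
10,Small nectar-feeding wasps,Hymenoptera
11,Large ants,Hymenoptera
12,Small ants,Hymenoptera
13,Hovering beeflies,Diptera
14,Non-hovering beeflies,Diptera
15,Long-tongued flies,Diptera
16,Large hoverflies,Diptera
17,Small hoverflies,Diptera
18,Large flies,Diptera
19,Small flies,Diptera
20,Large butterflies,Lepidoptera
21,Small butterflies,Lepidoptera
22,Hawkmoths,Lepidoptera
23,Small moths,Lepidoptera
24,Large beetles,Coleoptera
25,Small beetles,Coleoptera
26,Small diving beetles,Coleoptera
27,Aphids,Others
28,Bugs,Others
29,Thrips,Others
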