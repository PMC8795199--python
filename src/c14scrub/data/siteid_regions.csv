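kind,prefix,province
smithsonian,1,Alabama
smithsonian,2,Arizona
smithsonian,3,Arkansas
smithsonian,4,California
smithsonian,5,Colorado
smithsonian,6,Connecticut
smithsonian,7,Delaware
smithsonian,8,Florida
smithsonian,9,Georgia
smithsonian,10,Idaho
smithsonian,11,Illinois
smithsonian,12,Indiana
smithsonian,13,Iowa
smithsonian,14,Kansas
smithsonian,15,Kentucky
smithsonian,16,Louisiana
smithsonian,17,Maine
smithsonian,18,Maryland
smithsonian,19,Massachusetts
smithsonian,20,Michigan
smithsonian,21,Minnesota
smithsonian,22,Mississippi
smithsonian,23,Missouri
smithsonian,24,Montana
smithsonian,25,Nebraska
smithsonian,26,Nevada
smithsonian,27,New Hampshire
smithsonian,28,New Jersey
smithsonian,29,New Mexico
smithsonian,30,New York
smithsonian,31,North Carolina
smithsonian,32,North Dakota
smithsonian,33,Ohio
smithsonian,34,Oklahoma
smithsonian,35,Oregon
smithsonian,36,Pennsylvania
smithsonian,37,Rhode Island
smithsonian,38,South Carolina
smithsonian,39,South Dakota
smithsonian,40,Tennessee
smithsonian,41,Texas
smithsonian,42,Utah
smithsonian,43,Vermont
smithsonian,44,Virginia
smithsonian,45,Washington
smithsonian,46,West Virginia
smithsonian,47,Wisconsin
smithsonian,48,Wyoming
smithsonian,49,Alaska
smithsonian,50,Hawaii
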