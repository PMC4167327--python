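state,year,black,white,citation,flag
IL,1975,12.1,4.4,"Results, Illinois",
IL,2010,5.7,2.2,"Results, Illinois",
MD,1975,14.8,6.2,"Results, Maryland",
MD,2010,2.9,1.6,"Results, Maryland",
MS,1975,9.7,3.9,"Results, Mississippi",
MS,2010,6.2,2.5,"Results, Mississippi",
NY,1975,13.4,4.4,"Results, New York",
NY,2010,3.2,2.0,"Results, New York",
NC,1975,17.5,4.9,"Results, North Carolina",
NC,2010,3.7,1.6,"Results, North Carolina",
PA,1975,9.7,4.7,"Results, Pennsylvania",
PA,2010,3.9,1.8,"Results, Pennsylvania",
SC,1975,14.9,4.4,"Results, South Carolina",
SC,2010,4.3,2.4,"Results, South Carolina",
TN,1975,17.3,6.0,"Results, Tennessee",
TN,2010,3.2,2.3,"Results, Tennessee",
TX,1975,13.8,5.1,"Results, Texas","narrative's White decline of 5% is inconsistent with 5.1 -> 2.5 (51%)"
TX,2010,4.9,2.5,"Results, Texas","narrative's White decline of 5% is inconsistent with 5.1 -> 2.5 (51%)"
ALL,1975,13.95,4.88,"Combined mortality for 13 states; Tables 3-4 1975 means",
ALL,2010,4.20,2.24,"Combined mortality for 13 states; Tables 3-4 2010 means",
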