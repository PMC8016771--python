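alpha2,name,region,aliases
AL,Albania,Southern Europe,
AD,Andorra,Southern Europe,
AT,Austria,Western Europe,
BY,Belarus,Eastern Europe,
BE,Belgium,Western Europe,
BA,Bosnia and Herzegovina,Southern Europe,Bosnia
BG,Bulgaria,Eastern Europe,
HR,Croatia,Southern Europe,
CZ,Czechia,Eastern Europe,Czech Republic
DK,Denmark,Northern Europe,
EE,Estonia,Northern Europe,
FI,Finland,Northern Europe,
FR,France,Western Europe,
DE,Germany,Western Europe,
GR,Greece,Southern Europe,
HU,Hungary,Eastern Europe,
IS,Iceland,Northern Europe,
IE,Ireland,Northern Europe,
IT,Italy,Southern Europe,
LV,Latvia,Northern Europe,
LI,Liechtenstein,Western Europe,
LT,Lithuania,Northern Europe,
LU,Luxembourg,Western Europe,
MT,Malta,Southern Europe,
MD,Republic of Moldova,Eastern Europe,Moldova
MC,Monaco,Western Europe,
ME,Montenegro,Southern Europe,
NL,Netherlands,Western Europe,The Netherlands|Holland
MK,North Macedonia,Southern Europe,Macedonia
NO,Norway,Northern Europe,
PL,Poland,Eastern Europe,
PT,Portugal,Southern Europe,
RO,Romania,Eastern Europe,
RU,Russian Federation,Eastern Europe,Russia
SM,San Marino,Southern Europe,
RS,Serbia,Southern Europe,
SK,Slovakia,Eastern Europe,
SI,Slovenia,Southern Europe,
ES,Spain,Southern Europe,
SE,Sweden,Northern Europe,
CH,Switzerland,Western Europe,
UA,Ukraine,Eastern Europe,
GB,United Kingdom,Northern Europe,UK|Great Britain|United Kingdom of Great Britain and Northern Ireland
AR,Argentina,Non-Europe,
AU,Australia,Non-Europe,
BR,Brazil,Non-Europe,
CA,Canada,Non-Europe,
CN,China,Non-Europe,
EG,Egypt,Non-Europe,
IL,Israel,Non-Europe,
IN,India,Non-Europe,
JP,Japan,Non-Europe,
KR,Republic of Korea,Non-Europe,South Korea
MA,Morocco,Non-Europe,
MX,Mexico,Non-Europe,
NZ,New Zealand,Non-Europe,
TR,Turkey,Non-Europe,Türkiye
US,United States of America,Non-Europe,United States|USA
ZA,South Africa,Non-Europe,
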