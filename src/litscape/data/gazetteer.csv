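variant,country
usa,United States
u.s.a,United States
u.s.a.,United States
us,United States
u.s.,United States
united states,United States
united states of america,United States
america,United States
alabama,United States
al,United States
alaska,United States
ak,United States
arizona,United States
az,United States
arkansas,United States
ar,United States
california,United States
ca,United States
colorado,United States
co,United States
connecticut,United States
ct,United States
delaware,United States
de,United States
florida,United States
fl,United States
georgia,United States
ga,United States
hawaii,United States
hi,United States
idaho,United States
id,United States
illinois,United States
il,United States
indiana,United States
in,United States
iowa,United States
ia,United States
kansas,United States
ks,United States
kentucky,United States
ky,United States
louisiana,United States
la,United States
maine,United States
me,United States
maryland,United States
md,United States
massachusetts,United States
ma,United States
michigan,United States
mi,United States
minnesota,United States
mn,United States
mississippi,United States
ms,United States
missouri,United States
mo,United States
montana,United States
mt,United States
nebraska,United States
ne,United States
nevada,United States
nv,United States
new hampshire,United States
nh,United States
new jersey,United States
nj,United States
new mexico,United States
nm,United States
new york,United States
ny,United States
north carolina,United States
nc,United States
north dakota,United States
nd,United States
ohio,United States
oh,United States
oklahoma,United States
ok,United States
oregon,United States
or,United States
pennsylvania,United States
pa,United States
rhode island,United States
ri,United States
south carolina,United States
sc,United States
south dakota,United States
sd,United States
tennessee,United States
tn,United States
texas,United States
tx,United States
utah,United States
ut,United States
vermont,United States
vt,United States
virginia,United States
va,United States
washington,United States
wa,United States
west virginia,United States
wv,United States
wisconsin,United States
wi,United States
wyoming,United States
wy,United States
district of columbia,United States
dc,United States
uk,United Kingdom
u.k.,United Kingdom
united kingdom,United Kingdom
england,United Kingdom
scotland,United Kingdom
wales,United Kingdom
northern ireland,United Kingdom
great britain,United Kingdom
china,China
p.r. china,China
pr china,China
p. r. china,China
people's republic of china,China
peoples republic of china,China
republic of china,Taiwan
taiwan,Taiwan
japan,Japan
germany,Germany
deutschland,Germany
france,France
italy,Italy
italia,Italy
spain,Spain
españa,Spain
espana,Spain
canada,Canada
australia,Australia
netherlands,Netherlands
the netherlands,Netherlands
holland,Netherlands
switzerland,Switzerland
sweden,Sweden
norway,Norway
denmark,Denmark
finland,Finland
austria,Austria
belgium,Belgium
portugal,Portugal
greece,Greece
ireland,Ireland
poland,Poland
czech republic,Czech Republic
czechia,Czech Republic
slovakia,Slovakia
hungary,Hungary
romania,Romania
bulgaria,Bulgaria
croatia,Croatia
serbia,Serbia
slovenia,Slovenia
russia,Russia
russian federation,Russia
ukraine,Ukraine
turkey,Turkey
türkiye,Turkey
israel,Israel
saudi arabia,Saudi Arabia
united arab emirates,United Arab Emirates
uae,United Arab Emirates
qatar,Qatar
kuwait,Kuwait
iran,Iran
islamic republic of iran,Iran
iraq,Iraq
egypt,Egypt
south africa,South Africa
nigeria,Nigeria
kenya,Kenya
morocco,Morocco
tunisia,Tunisia
india,India
pakistan,Pakistan
bangladesh,Bangladesh
sri lanka,Sri Lanka
nepal,Nepal
south korea,South Korea
republic of korea,South Korea
korea,South Korea
north korea,North Korea
singapore,Singapore
malaysia,Malaysia
thailand,Thailand
vietnam,Vietnam
viet nam,Vietnam
indonesia,Indonesia
philippines,Philippines
hong kong,Hong Kong
macau,Macau
brazil,Brazil
brasil,Brazil
argentina,Argentina
chile,Chile
colombia,Colombia
peru,Peru
uruguay,Uruguay
venezuela,Venezuela
mexico,Mexico
méxico,Mexico
cuba,Cuba
new zealand,New Zealand
iceland,Iceland
luxembourg,Luxembourg
estonia,Estonia
latvia,Latvia
lithuania,Lithuania
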