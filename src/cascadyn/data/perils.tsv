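# Generic taxonomy of perils: 19 loss-generating event classes.
# Columns: id, name, origin, system. Row order is the canonical matrix index order
# (11 natural perils followed by 8 anthropogenic ones).
id	name	origin	system
EQ	Earthquake	geological/geomorphological	natural
VE	Volcanic eruption	geological/geomorphological	natural
MS	Mass slide	geological/geomorphological	natural
FL	Flood	hydrological	natural
WS	Windstorm	meteorological	natural
OS	Other storm	meteorological	natural
EW	Extreme weather	meteorological	natural
WF	Wildfire	biophysical/ecological	natural
DI	Disease	biophysical/ecological	natural
AI	Asteroid impact	extraterrestrial	natural
GS	Geomagnetic storm	extraterrestrial	natural
FI	Fire	technological	anthropogenic
CF	Critical infrastructure failure	technological	anthropogenic
NF	Critical network failure	technological	anthropogenic
BI	Business interruption	economical	anthropogenic
EC	Economic crisis	economical	anthropogenic
SU	Social unrest	social	anthropogenic
HD	Healthcare degradation	social	anthropogenic
CO	Conflict	social	anthropogenic
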