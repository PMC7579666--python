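# 29 historical catastrophes with rich and/or peculiar chains-of-events.
# Columns: case_id, name, country, trigger, pairs, raw_encoding.
# pairs holds the directed one-to-one interactions as SRC>TGT tokens separated by '|',
# tokenized mechanically from raw_encoding (which is preserved verbatim for audit).
# Token normalization (uppercasing, the ES->EC alias) happens at parse time, never here.
# Multi-variate consequences (the source's arrow-chains marked with a double arrow) are
# deliberately not encoded; only one-to-one pairs appear.
# The COVID-19 pandemic has no single country; 'WW' is used as a worldwide placeholder.
case_id	name	country	trigger	pairs	raw_encoding
tohoku2011	2011 Tohoku	JP	EQ	EQ>FL|FL>CF|CF>NF|CF>BI	(EQ, FL); (FL, CF); (CF, NF); (CF, BI)
wenchuan2008	2008 Wenchuan	CN	EQ	EQ>MS|MS>FL|FL>FL|EQ>NF|NF>BI|NF>CF|CF>FI|MS>NF|NF>HD|EQ>CF|CF>DI|EQ>BI	(EQ, MS); (MS, FL); (FL; FL); (EQ, NF); (NF, BI); (NF; CF); (CF, FI); (MS, NF); (NF, HD); (EQ, CF); (CF, DI); (EQ, BI)
sumatra2004	2004 Sumatra	ID	EQ	EQ>FL|FL>NF|FL>HD|FL>BI|EQ>EQ|EQ>VE	(EQ, FL); (FL, NF); (FL, HD); (FL, BI); (EQ, EQ); (EQ, VE)
northridge1994	1994 Northridge	US	EQ	EQ>MS|MS>DI	(EQ, MS); (MS, DI)
kanto1923	1923 Kanto	JP	EQ	EQ>NF|NF>FI|FI>SU|NF>HD|HD>DI	(EQ, NF); (NF, FI); (FI, SU); (NF, HD); (HD, DI)
sanfrancisco1906	1906 San Francisco	US	EQ	EQ>NF|NF>FI	(EQ, NF); (NF, FI)
eyjafjallajokull2010	2010 Eyjafjallajokull	IS	VE	VE>NF|NF>BI	(VE, NF); (NF, BI)
stromboli2002	2002 Stromboli	IT	VE	VE>MS|MS>FL|FL>BI	(VE, MS); (MS, FL); (FL, BI)
laki1783	1783 Laki	IS	VE	VE>EW|EW>BI|VE>OS|OS>DI|OS>BI|BI>HD	(VE, EW); (EW, BI); (VE, OS); (OS, DI); (OS, BI); (BI, HD)
vajont1963	1963 Vajont	IT	MS	MS>FL|FL>CF	(MS, FL); (FL; CF)
thailand2011	2011 Thailand	TH	FL	FL>BI|BI>ES|BI>NF|NF>BI	(FL, BI); (BI, ES); (BI, NF); (NF, BI)
harvey2017	2017 Hurricane Harvey	US	WS	WS>OS|OS>FL|FL>NF|NF>HD	(WS, OS); (OS, FL); (FL, NF); (NF, HD)
sandy2012	2012 Hurricane Sandy	US	WS	WS>FL|FL>NF|NF>HD|FL>BI|BI>NF|NF>NF	(WS, FL); (FL, NF); (NF; HD); (FL, BI); (BI, NF); (NF, NF)
katrina2005	2005 Hurricane Katrina	US	WS	WS>FL|FL>CF|CF>BI|CF>NF|NF>HD|HD>SU	(WS, FL); (FL; CF); (CF, BI); (CF, NF); (NF, HD); (HD, SU)
icestorm2008	2008 southern China ice storm	CN	OS	OS>NF|NF>NF|NF>BI|NF>HD	(OS, NF); (NF, NF); (NF, BI); (NF, HD)
nyc1977	1977 New York City thunderstorm	US	OS	OS>NF|NF>NF|NF>HD|NF>SU|SU>FI|FI>BI	(OS, NF); (NF, NF); (NF, HD); (NF; SU); (SU, FI); (FI, BI)
syria2006	2006-2010 Syrian drought	SY	EW	EW>BI|BI>HD|HD>DI|BI>ES|ES>SU	(EW, BI); (BI, HD); (HD, DI); (BI, ES); (ES, SU)
bushfires2019	2019-2020 bushfires	AU	WF	WF>WF|WF>NF|WF>BI|NF>BI|BI>BI|WF>DI	(WF, WF); (WF, NF); (WF, BI); (NF, BI); (BI, BI); (WF, DI)
covid2020	2020 COVID-19	WW	DI	DI>HD|DI>NF|NF>BI|BI>ES|BI>BI|NF>SU|DI>DI	(DI, HD); (DI, NF); (NF, BI); (BI, ES); (BI, BI); (NF, SU); (DI, DI)
tunguska1908	1908 Tunguska	RU	AI	AI>WF|AI>WS	(AI, WF); (AI, WS)
quebec1989	1989 Quebec	CA	GS	GS>NF|NF>BI|BI>ES	(GS, NF); (NF, BI); (BI, ES)
basel1986	1986 Basel	CH	FI	FI>CF|CF>NF	(FI, CF); (CF, NF)
chernobyl1986	1986 Chernobyl	UA	CF	CF>DI|CF>BI|CF>FI	(CF, DI); (CF, BI); (CF, FI)
bhopal1984	1984 Bhopal	IN	CF	CF>DI|DI>BI|BI>ES|BI>NF|CF>BI|CF>SU	(CF, DI); (DI, BI); (BI, ES); (BI, NF); (CF, BI); (CF, SU)
seveso1976	1976 Seveso	IT	CF	CF>DI|CF>BI	(CF, DI); (CF, BI)
blackout2003it	2003 blackout	IT	NF	NF>NF|NF>NF	(NF, NF); (NF, NF)
blackout2003us	2003 blackout	US	NF	NF>NF|NF>BI	(NF, NF); (NF, BI)
lariot1992	1992 Los Angeles riot	US	SU	SU>FI|FI>BI|SU>BI|SU>SU|SU>HD	(SU, FI); (FI, BI); (SU, BI); (SU, SU); (SU, HD)
sept11attack2001	11 September 2001 terrorist attack	US	CO	CO>BI|BI>ES|CO>CO	(CO, BI); (BI, ES); (CO, CO)
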