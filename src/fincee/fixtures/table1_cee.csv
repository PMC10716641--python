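behavioural_state,cee_type,subject_id,cee_date,cee_number,pre_start,exposure_start,exposure_min,post_start,prey_mapping
deep-feeding,CONTROL,20160914_B020-BP,2016-09-16,2016_04,1323,1353,30,1423,no
deep-feeding,MFAS,bp10_236a,2010-08-24,2010_03,1120,1150,30,1220,no
deep-feeding,MFAS,bp10_239a,2010-08-27,2010_05,1204,1234,30,1304,no
deep-feeding,MFAS,bp13_216a,2013-08-04,2013_11,1539,1609,19,1628,yes
deep-feeding,MFAS,bp16_256a,2016-09-12,2016_03,1512,1542,30,1612,yes
deep-feeding,MFAS,20160912_B014-BP,2016-09-12,2016_03,1512,1542,30,1612,no
deep-feeding,PRN,bp10_245a,2010-09-02,2010_11,1322,1352,30,1422,no
deep-feeding,PRN,bp10_247a,2010-09-04,2010_13,1314,1344,30,1414,no
deep-feeding,PRN,bp12_217a,2012-08-04,2012_03,1422,1452,30,1522,yes
shallow-feeding,CONTROL,bp13_258a,2013-09-15,2013_15,1252,1322,30,1352,yes
shallow-feeding,CONTROL,bp13_258b,2013-09-15,2013_15,1252,1322,30,1352,yes
shallow-feeding,CONTROL,bp13_258c,2013-09-15,2013_15,1252,1322,30,1352,no
shallow-feeding,CONTROL,bp13_265a,2013-09-22,2013_19,1312,1342,30,1412,no
shallow-feeding,MFAS,bp13_257b,2013-09-14,2013_14,1530,1600,30,1630,yes
shallow-feeding,MFAS,bp13_259a,2013-09-16,2013_16,1046,1116,30,1146,yes
shallow-feeding,MFAS,bp15_236a,2015-08-24,2015_06,1357,1427,30,1457,yes
non-feeding,CONTROL,bp14_259a,2014-09-16,2014_08,1322,1352,30,1422,yes
non-feeding,MFAS,bp10_236b,2010-08-24,2010_03,1120,1150,30,1220,no
non-feeding,MFAS,bp13_139a,2013-05-19,2013_01,0944,1014,30,1044,no
non-feeding,MFAS,bp15_229a,2015-08-17,2015_02,1211,1241,30,1311,yes
non-feeding,PRN,bp12_294a,2012-10-20,2012_06,1416,1446,30,1516,yes
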