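behavioural_state,cee_type,subject_id,cee_date,prey_pre,prey_post,csel_db,change,confidence,severity_score,description
deep-feeding,CONTROL,20160914_B020-BP,2016-09-16,no,no,,no,med,,
deep-feeding,MFAS,bp10_236a,2010-08-24,no,no,160,no,high,,
deep-feeding,MFAS,bp10_239a,2010-08-27,no,no,145,yes,med,2,brief changes in respiration rate; minor change in dive profile
deep-feeding,MFAS,bp13_216a,2013-08-04,yes,yes,153,no,med,,
deep-feeding,MFAS,bp16_256a,2016-09-12,yes,yes,162,no,med,,
deep-feeding,MFAS,20160912_B014-BP,2016-09-12,no,no,164,no,med,,
deep-feeding,PRN,bp10_245a,2010-09-02,no,no,166,no,med,,
deep-feeding,PRN,bp10_247a,2010-09-04,no,no,111,yes,high,6,moderate cessation in feeding; minor avoidance of source (5)
deep-feeding,PRN,bp12_217a,2012-08-04,yes,yes,153,no,high,,
shallow-feeding,CONTROL,bp13_258a,2013-09-15,yes,yes,,no,med,,
shallow-feeding,CONTROL,bp13_258b,2013-09-15,yes,yes,,no,high,,
shallow-feeding,CONTROL,bp13_258c,2013-09-15,yes,yes,,no,low,,
shallow-feeding,CONTROL,bp13_265a,2013-09-22,no,no,,no,med,,no change identified according to specified criteria but groups noted onset of foraging during CEE
shallow-feeding,MFAS,bp13_257b,2013-09-14,yes,no,105,yes,low,4,minor avoidance of source
shallow-feeding,MFAS,bp13_259a,2013-09-16,yes,yes,156,no,med,,
shallow-feeding,MFAS,bp15_236a,2015-08-24,yes,yes,156,no,high,,
non-feeding,CONTROL,bp14_259a,2014-09-16,yes,yes,,no,med,,
non-feeding,MFAS,bp10_236b,2010-08-24,no,no,129,yes,med,4,minor avoidance of source
non-feeding,MFAS,bp13_139a,2013-05-19,no,no,149,no,med,,
non-feeding,MFAS,bp15_229a,2015-08-17,yes,no,151,no,high,,
non-feeding,PRN,bp12_294a,2012-10-20,yes,yes,101,yes,high,,moderate change in diving behaviour
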