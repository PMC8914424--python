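label,category,amount,country
ERCP,primary-intervention,413.42,KR
EUS-BD,primary-intervention,1028.27,KR
PTBD,primary-intervention,762.80,KR
Second PTBD for metal stent insertion,primary-intervention,350.82,KR
Second ERCP,secondary-intervention,206.76,KR
PTBD another site,secondary-intervention,762.80,KR
Tubography,secondary-intervention,141.39,KR
PTBD tube change,secondary-intervention,292.78,KR
Basic hospital cost per day,hospital-day,74.25,KR
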