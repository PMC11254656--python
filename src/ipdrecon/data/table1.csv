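arm_id,study,regimen,n_patients,pfs_events,os_events,median_pfs_months,median_os_months,median_followup_months
impower133_atezo,IMpower133,Atezolizumab + EC,201,171,138,5.2,12.3,22.9
caspian_durva,CASPIAN,Durvalumab + EP/EC,268,234,210,5.1,12.9,25.1
capstone1_adebrelimab,CAPSTONE-1,Adebrelimab + EC,230,175,151,5.8,15.3,13.5
skyscraper02_atezo,SKYSCRAPER-02,Placebo + atezolizumab + EC,201,170,105,5.6,13.6,14.3
keynote604_pembro,KEYNOTE-604,Pembrolizumab + EP/EC,228,188,169,4.5,10.8,21.6
rationale312_tisle,RATIONALE-312,Tislelizumab + EP/EC,227,175,164,4.8,15.5,14.2
astrum005_serplu,ASTRUM-005,Serplulimab + EC,389,223,146,5.7,15.4,12.3
extentorch_toripa,EXTENTORCH,Toripalimab + EP,223,171,174,5.8,14.6,13.7
caspian_durva_treme,CASPIAN,Durvalumab + tremelimumab + EP/EC,268,229,207,4.9,10.4,25.1
skyscraper02_tira,SKYSCRAPER-02,Tiragolumab + atezolizumab + EC,196,170,107,5.4,13.6,14.3
eter701_benmel_anlo,ETER701,Benmelstobart + anlotinib + EC,246,146,95,6.93,19.32,14.0
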