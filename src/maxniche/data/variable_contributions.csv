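code,description,unit,model_contribution_pct
Bio1,Annual mean temperature,degC,40.48
Bio2,Mean diurnal temperature range,degC,0.40
Bio3,Isothermality (Bio2/Bio7) (x100),%,23.75
Bio12,Annual precipitation,mm,2.00
Bio13,Precipitation in the wettest month,mm,27.19
Bio14,Precipitation in the driest month,mm,5.85
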