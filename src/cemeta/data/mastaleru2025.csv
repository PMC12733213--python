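study_id,authors_label,pub_year,country,intervention,population_tag,age_group,model_type,qaly_gain,total_qaly,total_cost,incremental_cost,icer_per_qaly,currency_code,price_year,se_qaly_gain,se_incremental_cost
S01a,Lim et al.,2025,Singapore,Inclisiran+SoC,ASCVD,unknown,markov,0.79,8.33,51124.11,27534.38,53149.66,PPP-USD,2024,,
S01b,Lim et al.,2025,Singapore,Inclisiran+SoC,HeFH secondary,45-60,markov,0.94,10.29,61865.18,35527.60,53149.66,PPP-USD,2024,,
S01c,Lim et al.,2025,Singapore,Inclisiran+SoC,general primary prevention,>60,markov,0.65,11.77,48117.04,34527.11,53149.66,PPP-USD,2024,,
S01d,Lim et al.,2025,Singapore,Inclisiran+SoC,HeFH primary,45-60,markov,0.32,16.41,62429.68,51287.21,53149.66,PPP-USD,2024,,
S02a,Desai et al.,2022,USA,Inclisiran+SoC,ASCVD,>60,markov,0.43,9.84,154067.36,23051.88,55421.87,PPP-USD,2024,,
S02b,Desai et al.,2022,USA,Inclisiran+SoC,ASCVD,>60,markov,0.43,9.84,176040.53,46097.32,55421.87,PPP-USD,2024,,
S02c,Desai et al.,2022,USA,Inclisiran+SoC,ASCVD,>60,markov,0.43,9.84,199085.97,69142.77,55421.87,PPP-USD,2024,,
S03,Galactionova et al.,2022,Switzerland,Other,general primary prevention,>60,markov,0.291,11.42,134827.35,37402.95,235403.33,PPP-USD,2024,,
S04a,Morton et al.,2023,UK,Inclisiran,age-of-intervention scenario,<45,microsimulation,0.035,20.64,123542.66,1913544.06,3494536.89,PPP-USD,2024,,
S04b,Morton et al.,2023,UK,Inclisiran,age-of-intervention scenario,<45,microsimulation,0.034,18.35,113387.86,1815767.61,3286519.03,PPP-USD,2024,,
S04c,Morton et al.,2023,UK,Inclisiran,age-of-intervention scenario,45-60,microsimulation,0.027,15.54,99571.70,2115993.11,3710957.69,PPP-USD,2024,,
S04d,Morton et al.,2023,UK,Inclisiran,age-of-intervention scenario,45-60,microsimulation,0.015,12.15,81003.76,3422471.51,5417450.97,PPP-USD,2024,,
S05,Zhou et al.,2024,China,Inclisiran+statin,ASCVD,45-60,markov,0.21,9.42,23715.92,17675.23,83717.19,PPP-USD,2024,,
S06,Kam et al.,2020,Australia,Inclisiran+statin,ASCVD,>60,markov,0.468,7.40,46957.23,99544.70,100127.64,PPP-USD,2024,,
S07,Wang et al.,2025,China,Inclisiran,general primary prevention,unknown,markov,0.374,7.77,13259.00,8739.16,23366.74,PPP-USD,2024,,
S08a,Morton et al.,2025,Australia,Inclisiran,general primary prevention,unknown,microsimulation,0.1402,15.41,533269.62,902919.79,450256.67,PPP-USD,2024,,
S08b,Morton et al.,2025,UK,Inclisiran,general primary prevention,unknown,microsimulation,0.19665,18.20,881994489.92,524740.92,524740.92,PPP-USD,2024,,
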