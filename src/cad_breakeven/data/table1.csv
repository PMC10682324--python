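study_label,country,modality,cad_product,reading_mode,reader_label,no_cad_central,no_cad_dispersion_kind,no_cad_dispersion,no_cad_lo,no_cad_hi,with_cad_central,with_cad_dispersion_kind,with_cad_dispersion,with_cad_lo,with_cad_hi,diff_seconds,diff_ci_lo,diff_ci_hi,p_value
Hsu 2021,Taiwan,low_dose_CT,"ClearRead CT (Riverain Technologies, Miamisburg, OH, USA)",second_reader,,156,sd,34,,,197,sd,46,,,41,39,44,< 0.001
Vassallo 2019,Italy,CT,"M5L lung CAD on-demand, INFN",second_reader,,296,sd,80,,,329,sd,83,,,33,,,< 0.05
Hempel 2022,The Netherlands,CT,"Veye Chest v2.15.3, Aidence B.V., Amsterdam, NL",concurrent_reader,Reader 1,226.4,sd,113.2,,,150.8,sd,74.2,,,-75.6,,,< 0.001
Hempel 2022,The Netherlands,CT,"Veye Chest v2.15.3, Aidence B.V., Amsterdam, NL",concurrent_reader,Reader 2,320.8,sd,164.2,,,184.2,sd,125.3,,,-136.6,,,< 0.001
Jacobs 2021,USA,low_dose_CT,"Veolity Lung CAD, version 1.5, MeVis Medical Solutions",concurrent_reader,,160,iqr_bounds,,96,245,86,iqr_bounds,,51,141,-64,,,< 0.001
Hsu 2021,Taiwan,low_dose_CT,"ClearRead CT (Riverain Technologies, Miamisburg, OH, USA)",concurrent_reader,,156,sd,34,,,124,sd,25,,,-32,-44,-30,< 0.001
Kozuka 2020,Japan,CT,InferRead CT Lung,concurrent_reader,,186,none,,,,168,none,,,,-18,,,
Lo 2018,USA,low_dose_CT,"ClearRead CT Vessel Suppression, Riverain Technologies",concurrent_reader,,127.2,none,,,,95.6,none,,,,-31.6,-47.4,-15.9,< 0.01
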