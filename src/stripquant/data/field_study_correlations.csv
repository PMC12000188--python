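analyte,method,r,stars,ci_low,ci_high,n
Total Chlorine,visual,0.79,***,0.62,0.89,34
Total Chlorine,human_machine,0.91,***,0.83,0.95,34
Free Chlorine,visual,0.8,***,0.63,0.9,34
Free Chlorine,human_machine,0.89,***,0.79,0.94,34
Iron,visual,0.46,**,0.14,0.69,34
Iron,human_machine,0.86,***,0.74,0.93,34
Total Hardness,visual,0.76,***,0.57,0.87,34
Total Hardness,human_machine,0.85,***,0.72,0.92,34
Lead,visual,0.48,**,0.17,0.7,34
Lead,human_machine,0.83,***,0.68,0.91,34
pH,visual,0.8,***,0.63,0.9,34
pH,human_machine,0.82,***,0.67,0.91,34
Total Alkalinity,visual,0.65,***,0.4,0.81,34
Total Alkalinity,human_machine,0.81,***,0.65,0.9,34
Nitrite,visual,0.44,**,0.12,0.68,34
Nitrite,human_machine,0.78,***,0.6,0.88,34
Nitrate,visual,0.41,**,0.08,0.66,34
Nitrate,human_machine,0.7,***,0.47,0.84,34
Copper,visual,0.37,*,0.04,0.63,34
Copper,human_machine,0.75,***,0.55,0.87,34
Cyanuric Acid,visual,0.38,**,0.05,0.64,34
Cyanuric Acid,human_machine,0.6,***,0.33,0.78,34
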