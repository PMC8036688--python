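# Ecosystem-service value coefficients per unit area, units: 100 yuan/hm2/yr
# Regional (Anyang, Henan) equivalent-factor table; negative entries are
# net disservices of built land.
service,category,cultivated,woodland,grassland,water,built,unused
food production,provisioning,14.68,5.35,10.01,13.82,0.00,0.00
raw materials,provisioning,6.91,12.26,9.59,3.97,0.00,0.00
water supply,provisioning,0.35,6.39,3.37,143.19,-268.66,0.00
gas regulation,regulating,11.57,40.59,26.08,13.30,-45.60,0.35
climate regulation,regulating,6.22,121.43,63.82,39.56,0.00,0.00
environment purification,regulating,1.73,34.37,18.05,95.87,-46.35,1.73
hydrology regulation,regulating,46.64,60.63,32.65,1766.01,0.00,0.52
soil maintenance,supporting,17.79,49.40,33.60,16.06,0.00,0.35
nutrient circulation,supporting,2.07,3.80,2.94,1.21,0.00,0.00
biodiversity,supporting,2.25,44.91,23.58,44.05,0.00,0.35
aesthetic landscape,cultural,1.04,19.69,10.36,32.65,0.00,0.17
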