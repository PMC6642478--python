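subgroup,typical_g_day,price_per_100g,carbohydrate,protein,total_fat,free_sugar_frac,sat_frac,trans_frac,fiber,sodium,calcium,copper,iron,phosphorus,magnesium,zinc,niacin,vitamin_a,thiamin,riboflavin,vitamin_b6,vitamin_b12,vitamin_c,vitamin_d,vitamin_e,folate
leafy_vegetables,3.3,0.80,3.0,2.0,0.3,0.0,0.20,0.0,2.5,30,100,0.10,2.0,40,30,0.40,0.6,250,0.07,0.10,0.15,0.0,35,0.0,1.5,100
other_vegetables,112.9,0.40,6.0,1.5,0.2,0.0,0.20,0.0,2.2,20,35,0.08,0.7,35,15,0.30,0.7,150,0.06,0.05,0.12,0.0,20,0.0,0.6,40
tuber,22.3,0.25,18.0,1.8,0.1,0.0,0.20,0.0,2.0,10,12,0.10,0.8,50,22,0.30,1.3,2,0.09,0.03,0.25,0.0,12,0.0,0.05,20
fruits,69.1,0.50,13.0,0.8,0.3,0.0,0.20,0.0,2.2,2,15,0.10,0.3,20,12,0.10,0.5,50,0.04,0.04,0.30,0.0,40,0.0,0.4,20
beans,183.4,0.30,14.0,5.0,0.5,0.0,0.20,0.0,6.0,2,30,0.20,1.5,90,40,0.90,0.5,0,0.15,0.06,0.10,0.0,1,0.0,0.3,130
nuts,0.1,3.00,20.0,15.0,45.0,0.0,0.12,0.0,8.0,5,70,1.00,2.5,350,200,3.00,1.5,0,0.30,0.15,0.30,0.0,0.5,0.0,8.0,60
rice,161.2,0.20,28.0,2.5,0.2,0.0,0.25,0.0,0.6,1,3,0.05,0.4,35,12,0.50,1.5,0,0.08,0.02,0.09,0.0,0,0.0,0.05,4
whole_cereals,8.4,0.60,60.0,10.0,3.0,0.0,0.20,0.0,9.0,5,30,0.40,3.5,300,120,2.50,4.5,0,0.35,0.15,0.30,0.0,0,0.0,0.8,40
pasta,43.4,0.40,25.0,4.5,0.8,0.0,0.25,0.0,1.5,3,7,0.08,0.6,50,18,0.50,1.2,0,0.10,0.05,0.05,0.0,0,0.0,0.1,7
cake_cookies,27.1,0.90,55.0,6.0,15.0,0.45,0.40,0.08,1.5,300,40,0.10,1.5,100,15,0.50,1.5,50,0.10,0.10,0.04,0.1,0,0.3,1.0,30
breads,53.4,0.55,50.0,8.0,3.0,0.02,0.30,0.01,2.5,500,25,0.15,2.5,90,25,0.80,3.5,0,0.40,0.25,0.08,0.0,0,0.0,0.3,60
cheese,3.3,2.00,3.0,25.0,28.0,0.0,0.60,0.01,0.0,600,700,0.03,0.5,450,25,3.00,0.1,250,0.03,0.35,0.08,1.2,0,0.5,0.6,20
yogurt,5.8,0.90,15.0,3.5,2.5,0.40,0.60,0.01,0.0,50,120,0.01,0.1,95,11,0.50,0.1,30,0.03,0.20,0.04,0.4,1,0.5,0.05,7
nonfat_milk,4.4,0.35,5.0,3.4,0.2,0.0,0.50,0.0,0.0,45,120,0.01,0.05,95,11,0.40,0.1,60,0.04,0.18,0.04,0.5,1,1.0,0.02,5
milk,74.2,0.30,5.0,3.2,3.3,0.0,0.60,0.01,0.0,45,115,0.01,0.05,90,10,0.40,0.1,45,0.04,0.17,0.04,0.45,1,1.2,0.06,5
red_meat,78.5,1.50,0.0,26.0,15.0,0.0,0.40,0.01,0.0,60,10,0.10,2.6,200,22,6.00,5.0,5,0.07,0.20,0.35,2.5,0,0.2,0.2,8
chicken,39.4,0.80,0.0,27.0,8.0,0.0,0.28,0.01,0.0,75,13,0.07,1.1,190,25,1.80,8.0,15,0.07,0.15,0.40,0.3,0,0.1,0.3,6
processed_meat,5.7,1.40,2.0,14.0,25.0,0.0,0.38,0.02,0.0,1000,10,0.06,1.2,150,14,2.00,3.0,0,0.30,0.15,0.20,1.0,0,0.4,0.2,3
eggs,14.5,0.70,1.0,13.0,10.0,0.0,0.33,0.0,0.0,130,55,0.07,1.8,190,12,1.30,0.1,160,0.07,0.45,0.12,1.1,0,2.0,1.0,47
fish_seafood,45.5,1.60,0.0,22.0,6.0,0.0,0.25,0.0,0.0,80,30,0.08,0.8,220,32,0.80,6.0,20,0.08,0.10,0.40,3.5,0,7.0,1.0,10
margarine_butter,6.0,1.00,0.5,0.5,80.0,0.0,0.30,0.12,0.0,600,20,0.0,0.0,20,2,0.10,0.0,650,0.0,0.03,0.0,0.1,0,1.0,6.0,1
olive_oil,0.5,2.50,0.0,0.0,100.0,0.0,0.15,0.0,0.0,1,0,0.0,0.0,0,0,0.0,0.0,0,0.0,0.0,0.0,0.0,0,0.0,14.0,0
ssb,98.7,0.35,10.5,0.0,0.0,0.95,0.20,0.0,0.0,5,2,0.01,0.1,5,2,0.02,0.1,0,0.01,0.01,0.01,0.0,2,0.0,0.0,1
snacks,51.1,0.80,30.0,7.0,18.0,0.05,0.35,0.05,1.5,600,30,0.10,1.5,100,20,0.80,2.0,30,0.15,0.10,0.10,0.2,1,0.2,2.0,25
sweets,41.7,0.80,75.0,2.0,8.0,0.80,0.50,0.03,1.0,50,40,0.15,1.0,60,25,0.40,0.5,20,0.02,0.08,0.02,0.1,0.5,0.1,0.5,5
manioc_flour,16.5,0.30,80.0,1.5,0.5,0.0,0.25,0.0,6.0,10,60,0.10,1.5,100,40,0.60,1.0,0,0.08,0.03,0.08,0.0,2,0.0,0.1,15
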