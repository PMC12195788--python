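group,subgroup,energy_kcal,protein_g,carb_g,lipid_g
Whole Grains,"Rice, Wheat, Corn, and Others",711.46,22.14,117.95,15.61
Tubers or Starchy Vegetables,Potatoes and Cassava,76.00,2.06,16.30,0.25
Vegetables,All Types of Vegetables,136.55,4.44,18.77,4.87
Fruits,All Types of Fruits,178.18,2.41,40.65,2.04
Dairy Products,Whole Milk or Equivalents,256.00,13.20,18.80,14.80
Protein Sources,"Beef, Lamb, and Pork",29.21,3.58,0.00,1.59
Protein Sources,Chicken and Other Poultry,49.14,7.77,0.02,1.85
Protein Sources,Eggs,22.35,1.86,0.05,1.64
Protein Sources,Fish,34.14,6.55,0.00,0.67
Protein Sources,Legumes,131.55,9.47,16.86,0.40
Protein Sources,Nuts and Seeds,0.00,0.00,0.00,0.00
Added Fats,Unsaturated Oils,165.85,0.00,0.00,18.44
Added Fats,Saturated Oils,88.97,0.07,0.08,9.82
Added Sugars,All Types of Sugars,121.83,0.03,30.75,0.00
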