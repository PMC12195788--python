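group,subgroup,grams_per_day
Whole Grains,"Rice, Wheat, Corn, and Others",250
Tubers or Starchy Vegetables,Potatoes and Cassava,100
Vegetables,All Types of Vegetables,300
Fruits,All Types of Fruits,300
Dairy Products,Whole Milk or Equivalents,400
Protein Sources,"Beef, Lamb, and Pork",14
Protein Sources,Chicken and Other Poultry,29
Protein Sources,Eggs,15
Protein Sources,Fish,28
Protein Sources,Legumes,100
Protein Sources,Nuts and Seeds,50
Added Fats,Unsaturated Oils,20
Added Fats,Saturated Oils,11.8
Added Sugars,All Types of Sugars,31
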