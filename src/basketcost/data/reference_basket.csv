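group,subgroup,item,grams_consume,fti,grams_purchase_printed,fti_source
Whole Grains,"Rice, Wheat, Corn, and Others",Rice,28.14,2.5,11.26,national
Whole Grains,"Rice, Wheat, Corn, and Others",Bread,204.33,1,204.33,national
Whole Grains,"Rice, Wheat, Corn, and Others",Spaghetti,17.52,2.36,7.43,national
Tubers or Starchy Vegetables,Potatoes and Cassava,Potato,100.00,1.04,96.15,national
Vegetables,All Types of Vegetables,Tomatoes,67.72,0.83,81.59,national
Vegetables,All Types of Vegetables,Onion,39.77,0.78,50.99,national
Vegetables,All Types of Vegetables,Lemon,33.22,0.58,57.27,national
Vegetables,All Types of Vegetables,Carrot,28.17,0.94,29.97,national
Vegetables,All Types of Vegetables,Avocado,26.86,0.73,36.80,national
Vegetables,All Types of Vegetables,Corn,26.68,1.04,25.65,national
Vegetables,All Types of Vegetables,Lettuce,25.77,1,25.77,national
Vegetables,All Types of Vegetables,Sweet Pumpkin,17.19,0.7622,22.55,international
Vegetables,All Types of Vegetables,Bell Pepper,5.84,0.86,6.79,national
Vegetables,All Types of Vegetables,Chard,5.28,1.0192,5.18,international
Vegetables,All Types of Vegetables,Zucchini,4.87,0.931,5.23,international
Vegetables,All Types of Vegetables,Cucumber,4.82,0.76,6.34,national
Vegetables,All Types of Vegetables,Green Beans,2.79,0.98,2.85,national
Vegetables,All Types of Vegetables,Garlic,2.69,0.87,3.09,national
Vegetables,All Types of Vegetables,Beetroot,2.19,0.7812,2.81,international
Vegetables,All Types of Vegetables,Spinach,1.88,0.97,1.94,national
Vegetables,All Types of Vegetables,Cauliflower,1.80,0.93,1.94,national
Vegetables,All Types of Vegetables,Artichoke,1.12,1.17,0.96,national
Vegetables,All Types of Vegetables,Mushrooms,0.94,0.62,1.52,national
Vegetables,All Types of Vegetables,Asparagus,0.40,0.6405,0.62,international
Fruits,All Types of Fruits,Banana,86.41,0.66,130.92,national
Fruits,All Types of Fruits,Apple,54.84,0.83,66.07,national
Fruits,All Types of Fruits,Orange,37.73,0.73,51.69,national
Fruits,All Types of Fruits,Peach and Nectarines,22.59,0.75,30.12,national
Fruits,All Types of Fruits,Grapes,18.34,0.92,19.93,national
Fruits,All Types of Fruits,Mandarins,16.89,0.66,25.59,national
Fruits,All Types of Fruits,Strawberry,14.06,0.92,15.28,national
Fruits,All Types of Fruits,Melons,13.95,0.52,26.83,back-solved
Fruits,All Types of Fruits,Pears,11.71,0.85,13.78,national
Fruits,All Types of Fruits,Kiwi,6.50,0.82,7.92,national
Fruits,All Types of Fruits,Watermelon,5.14,0.52,9.88,national
Fruits,All Types of Fruits,Cherry,3.58,0.84,4.27,national
Fruits,All Types of Fruits,Plum,2.33,0.95,2.45,national
Fruits,All Types of Fruits,Prickly Pear,1.67,0.95,1.76,national
Fruits,All Types of Fruits,Cucumber,1.64,0.85,1.93,national
Fruits,All Types of Fruits,Mango,1.44,0.71,2.03,national
Fruits,All Types of Fruits,Apricot,0.53,0.95,0.56,national
Fruits,All Types of Fruits,Grapefruit,0.40,0.68,0.59,national
Fruits,All Types of Fruits,Cherimoya,0.25,1,0.25,national
Dairy Products,Whole Milk or Equivalents,Whole Milk,400.00,1,400.00,national
Protein Sources,"Beef, Lamb, and Pork",Ground Beef,4.99,0.6,8.32,national
Protein Sources,"Beef, Lamb, and Pork",Pork Chop,3.37,0.5609,6.00,international
Protein Sources,"Beef, Lamb, and Pork",Black Beef,2.70,0.64,4.21,national
Protein Sources,"Beef, Lamb, and Pork",Pork Pulp,1.95,0.73,2.67,national
Protein Sources,"Beef, Lamb, and Pork",Pork Ribs,1.00,0.286,3.49,international
Protein Sources,Chicken and Other Poultry,Chicken Thigh,17.81,0.5544,32.12,international
Protein Sources,Chicken and Other Poultry,Chicken Breast,8.33,0.5928,14.04,international
Protein Sources,Chicken and Other Poultry,Whole Chicken,2.55,0.507,5.02,international
Protein Sources,Chicken and Other Poultry,Turkey Thigh,0.17,0.672,0.25,international
Protein Sources,Chicken and Other Poultry,Turkey Breast,0.12,0.79,0.15,national
Protein Sources,Chicken and Other Poultry,Ground Turkey,0.03,0.79,0.04,national
Protein Sources,Eggs,Egg,15.00,0.9944,15.08,international
Protein Sources,Fish,Hake,14.98,0.3871,38.69,international
Protein Sources,Fish,Pomfret,11.18,0.4543,24.61,international
Protein Sources,Fish,Salmon,1.84,0.89,2.07,national
Protein Sources,Legumes,Dried Beans,67.60,1.4,48.28,national
Protein Sources,Legumes,Lentils,32.40,1.6,20.25,national
Protein Sources,Nuts and Seeds,Nuts and Seeds,0.00,1,0.00,national
Added Fats,Unsaturated Oils,Vegetable Oil,19.55,1,19.55,national
Added Fats,Unsaturated Oils,Olive Oil,0.45,1,0.45,national
Added Fats,Saturated Oils,Butter,11.80,1,11.80,national
Added Sugars,All Types of Sugars,Sugar,31.00,1,31.00,national
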