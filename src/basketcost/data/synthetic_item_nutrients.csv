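subgroup,item,energy_kcal_100g,protein_g_100g,carb_g_100g,lipid_g_100g
"Rice, Wheat, Corn, and Others",Rice,284.595384,8.856354,47.181887,6.24425
"Rice, Wheat, Corn, and Others",Bread,284.595384,8.856354,47.181887,6.24425
"Rice, Wheat, Corn, and Others",Spaghetti,284.595384,8.856354,47.181887,6.24425
Potatoes and Cassava,Potato,76.0,2.06,16.3,0.25
All Types of Vegetables,Tomatoes,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Onion,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Lemon,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Carrot,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Avocado,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Corn,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Lettuce,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Sweet Pumpkin,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Bell Pepper,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Chard,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Zucchini,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Cucumber,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Green Beans,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Garlic,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Beetroot,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Spinach,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Cauliflower,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Artichoke,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Mushrooms,45.516667,1.48,6.256667,1.623333
All Types of Vegetables,Asparagus,45.516667,1.48,6.256667,1.623333
All Types of Fruits,Banana,59.393333,0.803333,13.55,0.68
All Types of Fruits,Apple,59.393333,0.803333,13.55,0.68
All Types of Fruits,Orange,59.393333,0.803333,13.55,0.68
All Types of Fruits,Peach and Nectarines,59.393333,0.803333,13.55,0.68
All Types of Fruits,Grapes,59.393333,0.803333,13.55,0.68
All Types of Fruits,Mandarins,59.393333,0.803333,13.55,0.68
All Types of Fruits,Strawberry,59.393333,0.803333,13.55,0.68
All Types of Fruits,Melons,59.393333,0.803333,13.55,0.68
All Types of Fruits,Pears,59.393333,0.803333,13.55,0.68
All Types of Fruits,Kiwi,59.393333,0.803333,13.55,0.68
All Types of Fruits,Watermelon,59.393333,0.803333,13.55,0.68
All Types of Fruits,Cherry,59.393333,0.803333,13.55,0.68
All Types of Fruits,Plum,59.393333,0.803333,13.55,0.68
All Types of Fruits,Prickly Pear,59.393333,0.803333,13.55,0.68
All Types of Fruits,Cucumber,59.393333,0.803333,13.55,0.68
All Types of Fruits,Mango,59.393333,0.803333,13.55,0.68
All Types of Fruits,Apricot,59.393333,0.803333,13.55,0.68
All Types of Fruits,Grapefruit,59.393333,0.803333,13.55,0.68
All Types of Fruits,Cherimoya,59.393333,0.803333,13.55,0.68
Whole Milk or Equivalents,Whole Milk,64.0,3.3,4.7,3.7
"Beef, Lamb, and Pork",Ground Beef,208.493933,25.553176,0.0,11.349036
"Beef, Lamb, and Pork",Pork Chop,208.493933,25.553176,0.0,11.349036
"Beef, Lamb, and Pork",Black Beef,208.493933,25.553176,0.0,11.349036
"Beef, Lamb, and Pork",Pork Pulp,208.493933,25.553176,0.0,11.349036
"Beef, Lamb, and Pork",Pork Ribs,208.493933,25.553176,0.0,11.349036
Chicken and Other Poultry,Chicken Thigh,169.389866,26.783868,0.068942,6.377111
Chicken and Other Poultry,Chicken Breast,169.389866,26.783868,0.068942,6.377111
Chicken and Other Poultry,Whole Chicken,169.389866,26.783868,0.068942,6.377111
Chicken and Other Poultry,Turkey Thigh,169.389866,26.783868,0.068942,6.377111
Chicken and Other Poultry,Turkey Breast,169.389866,26.783868,0.068942,6.377111
Chicken and Other Poultry,Ground Turkey,169.389866,26.783868,0.068942,6.377111
Eggs,Egg,149.0,12.4,0.333333,10.933333
Fish,Hake,121.928571,23.392857,0.0,2.392857
Fish,Pomfret,121.928571,23.392857,0.0,2.392857
Fish,Salmon,121.928571,23.392857,0.0,2.392857
Legumes,Dried Beans,131.55,9.47,16.86,0.4
Legumes,Lentils,131.55,9.47,16.86,0.4
Nuts and Seeds,Nuts and Seeds,0.0,0.0,0.0,0.0
Unsaturated Oils,Vegetable Oil,829.25,0.0,0.0,92.2
Unsaturated Oils,Olive Oil,829.25,0.0,0.0,92.2
Saturated Oils,Butter,753.983051,0.59322,0.677966,83.220339
All Types of Sugars,Sugar,393.0,0.096774,99.193548,0.0
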