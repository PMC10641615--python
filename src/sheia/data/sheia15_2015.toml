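# Default component specification for the Swedish Healthy Eating Index for
# Adults 2015 (SHEIA15): nine components, six adequacy ("positive") and three
# moderation ("negative"), each scored as a ratio of intake to the
# sex-specific recommended intake, truncated to [0, 1].
#
# Recommended intakes follow the 2015 Swedish food-based dietary guidelines
# and NNR 2012: vegetables + fruit 500 g/day; seafood 250 g/week (2-3
# servings of 125 g, lower bound) expressed per day; whole grains 70/90 g/day
# (women/men); fibre 25/35 g/day; MUFA 10 E%; PUFA 5 E%; SFA at most 10 E%;
# red and processed meat at most 500 g/week; added sugar at most 10 E%.

name = "sheia15-2015"

[[component]]
name = "veg_fruit"
direction = "positive"
basis = "veg_fruit"
unit = "g/day"
recommended = { female = 500.0, male = 500.0 }

[[component]]
name = "seafood"
direction = "positive"
basis = "seafood"
unit = "g/day"
recommended = { female = 35.714285714285715, male = 35.714285714285715 }

[[component]]
name = "wholegrain"
direction = "positive"
basis = "wholegrain"
unit = "g/day"
recommended = { female = 70.0, male = 90.0 }

[[component]]
name = "fibre"
direction = "positive"
basis = "fibre"
unit = "g/day"
recommended = { female = 25.0, male = 35.0 }

[[component]]
name = "mufa"
direction = "positive"
basis = "mufa_e"
unit = "E%"
recommended = { female = 10.0, male = 10.0 }

[[component]]
name = "pufa"
direction = "positive"
basis = "pufa_e"
unit = "E%"
recommended = { female = 5.0, male = 5.0 }

[[component]]
name = "sfa"
direction = "negative"
basis = "sfa_e"
unit = "E%"
recommended = { female = 10.0, male = 10.0 }

[[component]]
name = "red_processed_meat"
direction = "negative"
basis = "red_processed_meat"
unit = "g/day"
recommended = { female = 71.42857142857143, male = 71.42857142857143 }

[[component]]
name = "added_sugar"
direction = "negative"
basis = "added_sugar_e"
unit = "E%"
recommended = { female = 10.0, male = 10.0 }
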