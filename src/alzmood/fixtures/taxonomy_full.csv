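class,subclass
Patient,Man
Patient,Woman
Patient,Ethnographic Data
State of mind,Disoriented
State of mind,Nervous
State of mind,Boring
State of mind,Wander
State of mind,Depressed
Patron,Walking
Patron,Stopped
Patron,Sitting
Gerontological Centers,Dining Area
Gerontological Centers,Sleeping Area
Gerontological Centers,Waiting room Area
Gerontological Centers,Bathroom Area
Gerontological Centers,Patio Area
Gerontological Centers,Garden Area
Gerontological Centers,Physical Therapy Area
Gerontological Centers,Manualidades Area
Gerontological Centers,Recreation Area
Gerontological Centers,Electrotherapy Area
Gerontological Centers,Street Area
Gerontological Centers,Corridor Area
Reception/Cognition-Attention,Orientation
Reception/Cognition-Attention,Sensation/Perception
Reception/Cognition-Attention,Cognition
Reception/Cognition-Attention,Communication
Activity/Rest-Rest/Sleep,Activity/Exercise
Activity/Rest-Rest/Sleep,Energy balance
Activity/Rest-Rest/Sleep,Cardiovascular/Pulmonary Response
Activity/Rest-Rest/Sleep,Self-care
Nutrition,Ingestion
Nutrition,Digestion
Nutrition,Absorption
Nutrition,Metabolism
Nutrition,Hydration
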