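class,subclass
Patient,Habit
Patient,Livelihoods
Patient,Town
Patient,Culture
Scene,Corridor
Scene,Courtyard
Scene,Dining room
Scene,Bathroom
Scene,Rooms
Scene,Physical therapy room
Scene,Electrotherapy room
Scene,Street
Scene,Bedroom
Scene,Crafts room
Scene,Garden
Scene,Recreation room
Pattern,Walking
Pattern,Sitting
Pattern,Standing
State,Bored
State,Disoriented
State,Depressed
State,Wandered
State,Nervous
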