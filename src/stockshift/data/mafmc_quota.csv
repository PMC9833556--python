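state,stock,quota_pct
Maine,black_sea_bass,0.4
New Hampshire,black_sea_bass,0.4
Massachusetts,black_sea_bass,15.6
Rhode Island,black_sea_bass,13.2
Connecticut,black_sea_bass,3.7
New York,black_sea_bass,8.6
New Jersey,black_sea_bass,20.1
Delaware,black_sea_bass,4.1
Maryland,black_sea_bass,8.9
Virginia,black_sea_bass,16.1
North Carolina,black_sea_bass,8.9
Maine,summer_flounder,0.05
New Hampshire,summer_flounder,0.0005
Massachusetts,summer_flounder,6.8
Rhode Island,summer_flounder,15.7
Connecticut,summer_flounder,2.3
New York,summer_flounder,7.6
New Jersey,summer_flounder,16.7
Delaware,summer_flounder,0.02
Maryland,summer_flounder,2
Virginia,summer_flounder,21.3
North Carolina,summer_flounder,27.4
Maine,scup,0.1
New Hampshire,scup,0
Massachusetts,scup,21.6
Rhode Island,scup,56.2
Connecticut,scup,3.2
New York,scup,15.8
New Jersey,scup,2.9
Delaware,scup,0
Maryland,scup,0
Virginia,scup,0.2
North Carolina,scup,0
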