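unit,is_total,n_cages,n_adults,n_pups,days,interval,events,contaminated_mouse_days,printed_cage_days,printed_mouse_days,printed_mouse_days_per_cage,printed_openings,consistent_cage_days,consistent_mouse_days,consistent_mouse_days_per_cage,consistent_openings
B-Room 1-Isolator 1,0,4,11,5,730,10,0,0,2920,11680,2920,292,1,1,1,1
B-Room 1-Isolator 2,0,4,10,5,730,10,0,0,2920,10950,2738,292,1,1,1,1
B-Room 1-Isolator 3,0,3,8,0,730,10,0,0,2190,5840,1947,219,1,1,1,1
B-Room 2-Isolator 4,0,4,11,10,730,10,0,0,2920,15330,3833,292,1,1,1,1
Total Pressurized Isolator,1,15,40,20,730,10,0,0,10950,43800,2920,1095,1,1,1,1
B-Room 1-Nested Isolation,0,28,65,11,730,10,2,50,20440,55480,1981,2440,1,1,1,0
E-Room 2-Nested Isolation,0,21,47,0,730,10,0,0,15330,34310,1633,1533,1,1,1,1
Total NesTiso sets,1,49,112,11,730,10,2,50,35770,81760,1807,3973,1,0,0,0
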