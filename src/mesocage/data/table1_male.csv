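tag,group,days_protocol,days_headfix,total_headfixes,total_hours,headfixes_per_day,minutes_per_day,go_success_last5,daily_trials_5day
2016080026,1,90,60,933,9.8,15.6,9.8,91.3,17.6
201608466,1,93,91,2440,26,26.8,17.1,87.8,46.8
201608468,1,93,93,8360,97.7,89.9,63,8.6,1615.2
201608481,1,92,91,2197,24.2,24.1,15.9,92.8,222.6
201609136,1,90,82,1469,16.1,17.9,11.8,56.5,335
201609336,1,93,90,1344,11.9,14.9,8,70.4,23
210608298,1,92,88,2369,25.4,26.9,17.3,95.2,209.8
2016090793,2,43,32,1397,11.5,43.7,21.6,41.4,162.4
2016090943,2,47,37,1118,9.2,30.2,14.9,34.6,184.8
2016091112,2,13,7,141,1.1,20.1,9.1,6.1,28
2016090629,3,36,34,763,9.4,22.4,16.5,78.3,196.2
2016090797,3,33,30,866,10.8,28.9,21.7,75.8,173.2
2016090882,3,14,12,170,2,14.2,9.8,62.3,96.6
2016090964,3,9,8,144,1.4,18,10.6,58.8,100.5
2016090965,3,35,31,1024,12.8,33,24.8,68.8,185.8
2016090985,3,36,34,2072,25.9,60.9,45.7,0.4,581
2016091183,3,13,12,288,3.2,24,15.9,40.7,130.2
2016080252,4,85,73,1314,14.6,18,12,74.9,74.8
201608423,4,91,84,2513,29.9,29.9,21.4,73.1,359.8
201608474,4,35,33,632,6.7,19.2,12.1,42.9,199
801010205,5,22,21,368,2.8,17.5,8,31.5,92.8
801010219,5,36,34,803,7,23.6,12.4,34.6,153.4
801010270,5,34,27,362,3,13.4,6.7,30.2,130.4
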