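tag,group,days_protocol,days_headfix,total_headfixes,total_hours,headfixes_per_day,minutes_per_day,go_success_last5,daily_trials_5day
801010240,6,83,62,953,9.9,13.4,9.6,42.9,78
2018121234,6,83,39,812,8.8,14.5,13.6,43.5,93.4
2018121244,6,83,57,818,8.1,11.9,8.6,30.6,123.4
2018121245,6,83,68,1308,14.2,18.4,12.5,36.8,125.4
2018121379,6,83,70,1532,16.2,21.6,13.9,34.4,148.2
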