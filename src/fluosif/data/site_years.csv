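site,year,crop,latitude,longitude,season_start,season_end,spectra_start,spectra_end
US-Ne2,2017,corn,41.1649,-96.4701,2017-05-08,2017-10-30,2017-07-15,2017-10-15
US-Ne2,2018,soybean,41.1649,-96.4701,2018-05-14,2018-10-19,2018-06-19,2018-10-14
US-Ne3,2017,corn,41.1797,-96.4397,2017-05-08,2017-10-30,2017-07-15,2017-09-17
US-Ne3,2018,soybean,41.1797,-96.4397,2018-05-14,2018-10-19,2018-07-08,2018-10-14
US-Ne3,2019,corn,41.1797,-96.4397,2019-04-27,2019-11-06,2019-05-03,2019-10-15
US-UiB,2019,miscanthus,40.0628,-88.1984,2019-04-01,2020-03-31,2019-05-09,2019-11-19
US-UiB,2020,miscanthus,40.0628,-88.1984,2020-04-01,2021-03-31,2020-05-11,2020-11-01
US-UiC,2016,soybean,40.0647,-88.1983,2016-05-27,2016-10-17,2016-08-07,2016-09-24
US-UiC,2017,corn,40.0647,-88.1983,2017-05-16,2017-11-02,2017-06-07,2017-10-29
US-UiC,2018,corn,40.0647,-88.1983,2018-05-08,2018-10-09,2018-06-28,2018-10-10
US-UiC,2019,soybean,40.0647,-88.1983,2019-05-17,2019-10-09,2019-06-05,2019-10-06
Reifsteck,2020,soybean,39.8824,-88.1546,2020-04-21,2020-10-03,2020-05-02,2020-10-02
Reifsteck,2021,corn,39.8824,-88.1546,2021-05-01,2021-09-26,2021-05-16,2021-09-11
Rund,2021,corn,40.0070,-88.2897,2021-04-26,2021-12-02,2021-05-30,2021-09-18
Reinhart,2021,corn,39.8887,-88.2140,2021-04-23,2021-09-25,2021-05-15,2021-09-21
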