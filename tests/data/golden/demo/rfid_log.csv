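2014-06-10 06:00:00,00DEADBEEF,AB12
2014-06-10 06:00:00,00DEADBEEF,AB12
2014-06-10 06:00:01,00DEADBEEF,AB12
2014-06-10 06:00:01,00DEADBEEF,AB12
2014-06-10 06:05:16,00F17A23C5,AB12
2014-06-10 06:05:17,00F17A23C5,AB12
2014-06-10 06:07:35,00A94D10B7,AB12
2014-06-10 06:07:36,00A94D10B7,AB12
2014-06-10 06:07:36,00A94D10B7,AB12
2014-06-10 06:07:37,00A94D10B7,AB12
2014-06-10 06:07:37,00A94D10B7,AB12
2014-06-10 06:07:38,00A94D10B7,AB12
2014-06-10 06:07:38,00A94D10B7,AB12
2014-06-10 06:07:39,00A94D10B7,AB12
2014-06-10 06:07:39,00A94D10B7,AB12
2014-06-10 06:07:40,00A94D10B7,AB12
2014-06-10 06:07:40,00A94D10B7,AB12
2014-06-10 06:07:41,00A94D10B7,AB12
2014-06-10 06:07:41,00A94D10B7,AB12
2014-06-10 06:07:42,00A94D10B7,AB12
2014-06-10 06:07:42,00A94D10B7,AB12
2014-06-10 06:07:43,00A94D10B7,AB12
2014-06-10 06:07:43,00A94D10B7,AB12
2014-06-10 06:07:44,00A94D10B7,AB12
2014-06-10 06:07:44,00A94D10B7,AB12
2014-06-10 06:07:45,00A94D10B7,AB12
2014-06-10 06:07:45,00A94D10B7,AB12
2014-06-10 06:07:46,00A94D10B7,AB12
2014-06-10 06:07:46,00A94D10B7,AB12
2014-06-10 06:07:47,00A94D10B7,AB12
2014-06-10 06:07:47,00A94D10B7,AB12
2014-06-10 06:07:48,00A94D10B7,AB12
2014-06-10 06:07:48,00A94D10B7,AB12
2014-06-10 06:07:49,00A94D10B7,AB12
2014-06-10 06:07:49,00A94D10B7,AB12
2014-06-10 06:07:50,00A94D10B7,AB12
2014-06-10 06:07:50,00A94D10B7,AB12
2014-06-10 06:07:51,00A94D10B7,AB12
2014-06-10 06:07:51,00A94D10B7,AB12
2014-06-10 06:09:46,00F17A23C5,AB12
2014-06-10 06:09:46,00F17A23C5,AB12
2014-06-10 06:09:47,00F17A23C5,AB12
2014-06-10 06:09:47,00F17A23C5,AB12
2014-06-10 06:18:41,00A94D10B7,AB12
2014-06-10 06:18:42,00A94D10B7,AB12
2014-06-10 06:18:42,00A94D10B7,AB12
2014-06-10 06:18:43,00A94D10B7,AB12
2014-06-10 06:18:43,00A94D10B7,AB12
2014-06-10 06:18:44,00A94D10B7,AB12
2014-06-10 06:18:44,00A94D10B7,AB12
2014-06-10 06:21:36,00A94D10B7,AB12
2014-06-10 06:21:37,00A94D10B7,AB12
2014-06-10 06:21:37,00A94D10B7,AB12
2014-06-10 06:21:38,00A94D10B7,AB12
2014-06-10 06:21:38,00A94D10B7,AB12
2014-06-10 06:21:39,00A94D10B7,AB12
2014-06-10 06:21:39,00A94D10B7,AB12
2014-06-10 06:21:40,00A94D10B7,AB12
2014-06-10 06:21:40,00A94D10B7,AB12
2014-06-10 06:21:41,00A94D10B7,AB12
2014-06-10 06:21:41,00A94D10B7,AB12
2014-06-10 06:21:42,00A94D10B7,AB12
2014-06-10 06:21:42,00A94D10B7,AB12
2014-06-10 06:21:43,00A94D10B7,AB12
2014-06-10 06:21:43,00A94D10B7,AB12
2014-06-10 06:21:44,00A94D10B7,AB12
2014-06-10 06:21:44,00A94D10B7,AB12
2014-06-10 06:21:45,00A94D10B7,AB12
2014-06-10 06:21:45,00A94D10B7,AB12
2014-06-10 06:21:46,00A94D10B7,AB12
2014-06-10 06:21:46,00A94D10B7,AB12
2014-06-10 06:21:47,00A94D10B7,AB12
2014-06-10 06:21:47,00A94D10B7,AB12
2014-06-10 06:21:48,00A94D10B7,AB12
2014-06-10 06:21:48,00A94D10B7,AB12
2014-06-10 06:21:49,00A94D10B7,AB12
2014-06-10 06:21:49,00A94D10B7,AB12
2014-06-10 06:21:50,00A94D10B7,AB12
2014-06-10 06:21:50,00A94D10B7,AB12
2014-06-10 06:21:51,00A94D10B7,AB12
2014-06-10 06:21:54,00F17A23C5,AB12
2014-06-10 06:21:54,00F17A23C5,AB12
2014-06-10 06:21:55,00F17A23C5,AB12
2014-06-10 06:21:55,00F17A23C5,AB12
2014-06-10 06:21:56,00F17A23C5,AB12
2014-06-10 06:21:56,00F17A23C5,AB12
2014-06-10 06:25:39,00F17A23C5,AB12
2014-06-10 06:25:40,00F17A23C5,AB12
2014-06-10 06:25:40,00F17A23C5,AB12
2014-06-10 06:25:41,00F17A23C5,AB12
2014-06-10 06:25:41,00F17A23C5,AB12
2014-06-10 06:27:54,00F17A23C5,AB12
2014-06-10 06:27:55,00F17A23C5,AB12
2014-06-10 06:27:55,00F17A23C5,AB12
2014-06-10 06:27:56,00F17A23C5,AB12
2014-06-10 06:27:57,00F17A23C5,AB12
2014-06-10 06:27:58,00F17A23C5,AB12
2014-06-10 06:27:58,00F17A23C5,AB12
2014-06-10 06:27:59,00F17A23C5,AB12
2014-06-10 06:27:59,00F17A23C5,AB12
2014-06-10 06:29:44,00A94D10B7,AB12
2014-06-10 06:29:45,00A94D10B7,AB12
2014-06-10 06:29:45,00A94D10B7,AB12
2014-06-10 06:29:46,00A94D10B7,AB12
2014-06-10 06:29:46,00A94D10B7,AB12
2014-06-10 06:29:47,00A94D10B7,AB12
2014-06-10 06:29:47,00A94D10B7,AB12
2014-06-10 06:36:50,00F17A23C5,AB12
2014-06-10 06:36:51,00F17A23C5,AB12
2014-06-10 06:36:51,00F17A23C5,AB12
2014-06-10 06:37:45,00F17A23C5,AB12
2014-06-10 06:37:45,00F17A23C5,AB12
2014-06-10 06:37:46,00F17A23C5,AB12
2014-06-10 06:40:08,00F17A23C5,AB12
2014-06-10 06:40:09,00F17A23C5,AB12
2014-06-10 06:40:09,00F17A23C5,AB12
2014-06-10 06:40:10,00F17A23C5,AB12
2014-06-10 06:40:10,00F17A23C5,AB12
2014-06-10 06:40:11,00F17A23C5,AB12
2014-06-10 06:40:11,00F17A23C5,AB12
2014-06-10 06:40:12,00F17A23C5,AB12
2014-06-10 06:40:12,00F17A23C5,AB12
2014-06-10 06:40:13,00F17A23C5,AB12
2014-06-10 06:40:13,00F17A23C5,AB12
2014-06-10 06:40:14,00F17A23C5,AB12
2014-06-10 06:40:14,00F17A23C5,AB12
2014-06-10 06:40:15,00F17A23C5,AB12
2014-06-10 06:40:28,00F17A23C5,AB12
2014-06-10 06:40:29,00F17A23C5,AB12
2014-06-10 06:40:29,00F17A23C5,AB12
2014-06-10 06:40:30,00F17A23C5,AB12
2014-06-10 06:40:30,00F17A23C5,AB12
2014-06-10 06:40:31,00F17A23C5,AB12
2014-06-10 06:48:38,00F17A23C5,AB12
2014-06-10 06:48:39,00F17A23C5,AB12
2014-06-10 06:48:39,00F17A23C5,AB12
2014-06-10 06:48:40,00F17A23C5,AB12
2014-06-10 06:48:40,00F17A23C5,AB12
2014-06-10 06:48:41,00F17A23C5,AB12
2014-06-10 06:48:54,00A94D10B7,AB12
2014-06-10 06:48:55,00A94D10B7,AB12
2014-06-10 06:48:55,00A94D10B7,AB12
2014-06-10 06:48:56,00A94D10B7,AB12
2014-06-10 06:48:56,00A94D10B7,AB12
2014-06-10 06:48:57,00A94D10B7,AB12
2014-06-10 06:48:57,00A94D10B7,AB12
2014-06-10 06:48:58,00A94D10B7,AB12
2014-06-10 06:48:58,00A94D10B7,AB12
2014-06-10 06:57:31,00A94D10B7,AB12
2014-06-10 06:57:31,00A94D10B7,AB12
2014-06-10 06:57:32,00A94D10B7,AB12
2014-06-10 06:57:32,00A94D10B7,AB12
2014-06-10 06:57:33,00A94D10B7,AB12
2014-06-10 06:57:33,00A94D10B7,AB12
2014-06-10 06:57:34,00A94D10B7,AB12
2014-06-10 06:57:34,00A94D10B7,AB12
2014-06-10 06:57:35,00A94D10B7,AB12
2014-06-10 06:57:35,00A94D10B7,AB12
2014-06-10 06:57:36,00A94D10B7,AB12
2014-06-10 06:57:36,00A94D10B7,AB12
2014-06-10 06:57:37,00A94D10B7,AB12
2014-06-10 06:57:37,00A94D10B7,AB12
2014-06-10 06:57:38,00A94D10B7,AB12
2014-06-10 06:57:38,00A94D10B7,AB12
2014-06-10 06:57:39,00A94D10B7,AB12
2014-06-10 06:57:39,00A94D10B7,AB12
2014-06-10 06:57:40,00A94D10B7,AB12
2014-06-10 06:57:40,00A94D10B7,AB12
2014-06-10 06:57:41,00A94D10B7,AB12
2014-06-10 06:57:41,00A94D10B7,AB12
2014-06-10 06:57:42,00A94D10B7,AB12
2014-06-10 06:57:42,00A94D10B7,AB12
2014-06-10 06:57:43,00A94D10B7,AB12
2014-06-10 06:59:58,00DEADBEEF,AB12
2014-06-10 06:59:58,00DEADBEEF,AB12
2014-06-10 06:59:59,00DEADBEEF,AB12
2014-06-10 06:59:59,00DEADBEEF,AB12
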